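# Methods

`agonet` analyzes agonistic (fighting) interactions of group-housed pigs as
directed weighted networks, one per pen, and follows how individual animals'
network positions develop across three successive mixing events: weaning
into small flatdeck pens, rehousing into larger growing pens, and rehousing
of gilts into breeding pens. This note documents the model, the numerical
conventions, the synthetic data generator and the design choices that were
genuinely open.

## Event model and observation scheme

A fight event records pen, age level, the two animals, start time, duration
and a stand-off flag. When the flag is clear, the first animal is the
initiator (attacker) and the second the receiver; a stand-off is a fight
whose initiator and receiver could not be identified, and its participants
are treated as an unordered pair. Times are relative to the mixing day
(`D:HH:MM:SS`, day 1 = mixing day) because the analysis is aligned on
mixing, not on calendar dates.

Observation covers 17 hours over the two days after mixing: day 1
12:00–18:00 and day 2 07:00–18:00 (the night is excluded). Window
membership is start-inclusive and end-exclusive — the half-open convention
avoids double counting at shared boundaries. Fights shorter than the
1-second threshold are dropped; events are logged at second resolution, so
"longer than one second" is implemented as `duration >= 1 s` (the threshold
is configurable).

## Network construction

Each pen's events aggregate into one directed weighted graph over the full
pen roster — the roster matters because animals that never fought must
appear as isolated nodes with zero centrality, not vanish from the sample.
A clear fight adds weight 1 to the initiator→receiver edge. A stand-off
adds weight 0.5 to each of the two opposite edges, preserving the fight's
unit contribution while remaining agnostic about its direction. Edge
weights are therefore multiples of 0.5; they are stored as integer
half-units so that the conservation identity — total edge weight equals the
number of contributing events — is an exact integer statement checked in
the tests, not a floating-point approximation.

The undirected projection of a dyad sums its two directional weights. This
is a design choice (the collapse rule is not uniquely determined by the
problem): summation preserves each pair's total contact frequency and keeps
the conservation identity. The binary union (edge present iff any directed
edge present) is available by binarizing first.

## Centrality measures

Seven measures per animal, each binary and weighted (14 values):

* **Degree** — binary: distinct opponents; weighted: summed incident edge
  weight. **In/out-degree** — distinct attackers/victims, or summed
  incoming/outgoing weight. A reciprocal dyad counts as *one* opponent for
  binary total degree. Degree is reported unstandardized by default;
  dividing by n−1 is available behind a flag.
* **Betweenness** — for node v, the sum over ordered pairs (s,t), s≠t≠v, of
  σ_st(v)/σ_st (the fraction of shortest s→t paths through v; 0 when t is
  unreachable from s), divided by (n−1)(n−2) so the maximum is 1. Computed
  with Brandes' path-counting accumulation; tied shortest paths all count,
  with no tie-breaking. Networks with n < 3 have betweenness 0 everywhere.
* **Closeness** — for node u with r others reachable at summed distance d:
  `(r/(n−1)) · (r/d)`, the component-scaled form. Outgoing closeness uses
  forward distances (how quickly fights started by u can cascade through
  the pen), ingoing closeness uses reversed distances (how quickly the
  others' aggression reaches u), undirected closeness uses the summed-weight
  projection.

**Weighted distances.** On the weighted network an edge of weight w has
shortest-path length 1/w: frequent opponents are closer. Under this
convention weighted closeness of a strongly connected pair can exceed 1
(two animals fighting k times sit at distance 1/k), while weighted
betweenness — a count fraction — stays in [0, 1]. Binary variants use unit
lengths, so binary closeness and betweenness always lie in [0, 1].

**Disconnected networks.** Fight networks are routinely disconnected
(isolated non-fighters, one-directional chains). The component-scaled
closeness assigns 0 to isolates, keeps binary values in [0, 1], and
penalizes nodes that reach only a small fraction of the pen; the raw r/d
form is available via `scaling="off"`. This handling is an explicit
assumption of the package, chosen for its boundedness and its natural zero
for isolates.

**Numerics.** Binary traversals are breadth-first searches with integer
path counts. Weighted traversals are Dijkstra searches with float lengths;
two path lengths are considered tied when they differ by less than 1e-12
(relative). All edge lengths are positive, so shortest paths are simple and
predecessors settle before successors — path counts are exact integers.
The test suite verifies both variants against an independent brute-force
enumeration of all simple shortest paths (same tie convention) to 1e-9 on
hundreds of random graphs, and against networkx on graphs with dyadic
weights where float sums are exact.

## Rank statistics

With pens of 6–29 animals and strongly skewed, zero-inflated centrality
distributions, all inference is rank-based.

* **Kruskal-Wallis** across the three age levels, mid-ranks with the
  standard tie correction, chi-square reference with k−1 df. All-identical
  data give H = 0, p = 1. The implementation is cross-checked against
  scipy and against an exact permutation enumeration at tiny N.
* **Significance letters**: pairwise two-group Kruskal-Wallis tests
  (equivalent to rank-sum tests) at α = 0.05, no multiplicity correction
  (Bonferroni behind a flag); groups share a letter iff their pairwise test
  is non-significant, with maximal-clique labeling so intransitive patterns
  yield multi-letter labels such as "ab". If the global test is
  non-significant all groups share "a". The post-hoc procedure behind
  letter displays is a genuine design choice; pairwise rank tests at the
  nominal level are the simplest procedure consistent with the reporting
  style.
* **Spearman** correlations: Pearson correlation of mid-ranks, p from the
  t approximation on n−2 df. Zero rank variance flags the result; n = 3
  results are flagged low-n.

**Pooling.** The default analysis pools animals from all pens of an age
level as if independent, which matches the reporting style the package
emulates but is pseudo-replication: animals within a pen share the pen's
fight budget and are positively correlated. A pen-median mode (one
observation per pen) is available and is the statistically safer unit; see
Limitations.

Within-level correlation tables report binary-vs-weighted for each measure
and the documented pairs among the binary measures (in- vs out-degree,
degree family vs betweenness, degree family vs closeness family).
Cross-level correlations pair animals tracked at both levels of a
*consecutive* pair (weaned–growing, growing–gilt) only; non-consecutive
pairings are deliberately not produced.

## Synthetic study generator

No raw observation data are available for this kind of study, so the
package ships a generator that emulates the study's *structure* — group
counts and sizes, the 17-hour window, heterogeneous aggressiveness, trait
carry-over, stand-offs, and post-mixing decay — without claiming to
reproduce any particular study's exact numbers. Defaults, with rationale:

| parameter | default | rationale |
| --- | --- | --- |
| pens per level | 65 / 24 / 12 | study design scale |
| pen sizes | 6–11 / 20–25 / 18–29 | study design scale |
| mean initiated fights per animal | 6.0 / 2.5 / 2.5 | weaned pens fight at roughly twice the per-animal intensity of the older levels, putting the weighted-degree medians near a 2:1 ratio |
| trait dispersion (log sd) | 0.8 | log-normal multiplier on the Poisson rate; produces the very wide right tail (weighted degrees from 0 to ~50–100) that homogeneous Poisson cannot |
| cross-level trait correlation | 0.3 | consecutive-level carry-over of aggressiveness; induces observable out-degree rank correlations in the 0.15–0.25 range after Poisson attenuation |
| stand-off probability | 0.1 | a minority of fights lack an identifiable initiator; order-of-magnitude choice |
| temporal decay (per hour) | 0 / 0.1 / 0.1 | weaned fighting stays spread over both days; older levels concentrate fighting after mixing — 0.1/h puts ~80% of fights in the first six hours, a clear but not degenerate decline |

Counts are per-animal Poisson with the log-normal trait multiplier
(mean 1); victims are uniform among pen mates; fight times are drawn from
the observation windows thinned by exp(−decay·t) in hours since mixing, by
inverse-CDF sampling, so every generated event already lies inside a
window. At each later level a random subset of the previous population is
re-penned (largest groups shrink toward the range minimum if the drawn
sizes exceed the available animals; an infeasible partition is a
configuration error), and each animal's trait is resampled as
`z' = ρ z + sqrt(1−ρ²) ε` — same marginal, correlation ρ. A single seeded
random stream consumed in fixed level/pen order makes whole studies
byte-reproducible.

What the generator does *not* emulate: dominance hierarchies and
winner–loser dynamics, targeted opponent choice (a preferential option
exists but is off by default), pen-level environmental effects, and any
calibration to a specific study's medians. Tests passing on synthetic data
therefore demonstrate correctness of the pipeline's computations and
recovery of *structural* patterns (orderings, decay, carry-over), not
behavioral realism of pig aggression.

## Problem sizes used in the shipped checks

The acceptance checks run the full default design (101 pens, ~1350 animal
records, ~5000 events per replicate): 100 replicates for the age-level
ordering check, 200 per condition for the trait-carry-over recovery check,
100 pens per level for the temporal-decay check, and 200 random graphs of
up to 7 nodes for the brute-force centrality oracle. These sizes give
stable Monte-Carlo estimates while keeping a full run in the order of a
minute.

## Known limitations

* **Pooled inference is anti-conservative.** With ~550/540/280 pooled
  animals per level, pairwise rank tests detect even tiny distributional
  differences, and intra-pen correlation inflates their type-I error well
  above the nominal 5%. In replicate experiments, the growing and gilt
  levels — identical in distribution by construction — are spuriously
  split in a substantial fraction of runs under pooling, while pen-median
  mode restores the expected letter patterns for the degree and closeness
  families. Consequence: the shipped check that demands the full
  qualitative letter pattern (weaned a, older levels b,b on degree and
  closeness, no betweenness split) in ≥95 of 100 pooled-mode replicates
  fails, and is expected to fail under this design.
* **Betweenness is not flat across levels in the generator.** Small dense
  weaned networks have systematically higher normalized betweenness
  (mean ≈ 0.08) than larger sparse growing/gilt networks (≈ 0.06) under
  uniform victim choice. Real studies can show near-identical betweenness
  across levels; reproducing that would require opponent-choice structure
  the generator deliberately omits.
* The weighted-distance convention (1/w) and the component-scaled
  closeness are assumptions; alternative conventions change the weighted
  values (not the binary ones).
* Temporal information inside the two-day window is only used for
  filtering and timelines; the networks are aggregates.
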