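# Methods

This note documents the models, decision rules, parameters and numerical
choices implemented in `centrokit`, and what the synthetic test bed does
and does not establish.

## Data model and conventions

Sequences use the 20 standard amino-acid letters plus `X` (unknown; the
built-in predictors give it neutral parameters). All residue coordinates
are 1-based inclusive, matching predictor output files, and every file
the package writes states this in a `#` header. Per-residue tracks
(disorder, coiled-coil, secondary structure, modeled) are boolean or
{H,E,C} vectors aligned 1:1 with the sequence; imports that cannot align
(row count, residue letters) fail loudly and never truncate silently.
Eight-class DSSP states are collapsed H,G,I→H; E,B→E; else→C, the common
3-class convention. Each gene is represented by its longest isoform; ties
are broken by lexicographically smallest id so selection is
deterministic and idempotent.

Track provenance is explicit: `imported` (external predictor files) vs
`builtin` (the stand-in predictors below). Set-level statistics report
which sources fed them; the two are never mixed silently.

## Joint-annotation statistics

Set-level fractions are residue-weighted — pooled counts over all
residues of the set — because the quantities of interest are fractions
"of the residues" and proteins vary over two orders of magnitude in
length. Per-protein fraction distributions (for histogramming and the
">20% of length" census) are computed separately.

The dual-annotation propensity is
`ln P(c&d) − ln P(c) − ln P(d)`, in natural-log units, with `P(c)` the
full coiled-coil marginal (dual + coil-only). The natural logarithm is a
deliberate choice: it reproduces both published worked values (0.51 for
the study fractions 0.124/0.131/0.57 and 0.75 for the control fractions
0.033/0.040/0.39), whereas base-10 would give 0.22/0.33. A zero argument
makes the statistic undefined; the function raises rather than emitting
−inf, and pooled statistics report it as absent.

"Stretches" are maximal runs of true values *strictly* longer than the
threshold (default 20): a run of exactly 20 residues does not qualify.
All six decision thresholds in the package follow the same wording-level
strictness and are covered by boundary-value tests: runs >20; dual
coverage >20% of length; SMART evidence ≥30 residues (inclusive);
residual regions >40 residues; disordered-or-coil content <30%; identity
discard >40%.

Uncertainties come from a protein-level bootstrap (default 1000
replicates, seeded, bit-reproducible): residues within a protein are
strongly correlated, so resampling proteins is the honest unit. A
single-protein set still yields an SE but the comparison is flagged
unreliable.

## Domain segmentation

Each sequence is partitioned with priority SMART domain > coil stretch >
disorder stretch > residual; overlapping SMART intervals are merged into
their union (nested repeats are common). When a higher-priority interval
truncates a stretch, the strict run-length rule is re-applied to each
surviving piece; a piece that no longer qualifies reverts to residual.
The partition covers every residue exactly once (property-tested on
random layouts against an independently written re-derivation).

One consequence worth noting: the *partition* is not monotone in the
run-length threshold. Raising the threshold can disqualify a short coil
run, which then no longer truncates an overlapping long disorder run, so
total stretch coverage can grow. Monotonicity holds per track at the
stretch-extraction level, and that is where it is tested.

Globular calls: condition 1 accepts SMART intervals with significant
evidence spanning ≥30 residues; condition 2 accepts residual regions
strictly longer than 40 residues whose structural alignment has Z > 3
and whose disordered-or-coil fraction is strictly below 30%. The 30%
test counts a residue once if it is disordered OR coil (union); since the
stretch annotations were already removed from residual regions, double
counting would be hard to motivate, but an additive mode
(`disorder_coil_mode="sum"`) is available. An eligible region without an
alignment record is rejected with reason `missing_evidence` (logged),
never an exception. Calls with known-structure identity strictly above
40% are discarded as of little experimental interest; calls without an
identity record are retained.

## Template selection and coverage

Hits arrive via two channels with strict filters: `hmm` (probability
>0.95, span >30 residues, identity >0.20) and `high_identity` (identity
>0.70). The span filter (">30", strict) and the overlap rule ("at least
30 new residues", inclusive) are deliberately independent parameters —
the source wording differs — and both are configurable.

Selection is a greedy pass in a total order: identical-residue count
descending (round-half-up of identity × span when no explicit count is
given; an explicit count wins), then span descending, then template id.
The first hit is accepted; each later hit is accepted iff it contributes
≥30 query residues not yet covered. The order is total, so the output is
invariant to input permutation. The top-ranked hit is always covered;
the *longest* hit need not be (it can be out-ranked and contribute too
few new residues).

Coverage accounting reports per-protein modeled fractions and model
counts, the set-level modeled residue fraction, the accepted-fragment
identity histogram (10% bins, plus counts below 30% and above 90%), and
the 2×2 modeled × (disordered∨coil) residue cross-tab with all four
conditional fractions; degenerate conditionals are reported as absent,
never as 0. Fragments with identity ≥0.95 are flagged "retrieve" (one
would download the structure rather than model it); the 6-residue
untemplated-gap limit is recorded as metadata. No 3-D modeling is
performed.

## Interaction network

Metrics are computed on the undirected simple graph (duplicate edges and
self-loops are dropped on import, with counts logged). Betweenness is
unnormalized shortest-path betweenness over unordered pairs, endpoints
excluded, fractional credit across multiple shortest paths; pairs in
different components contribute nothing. It is computed with networkx
and verified in tests against an exhaustive enumeration of all shortest
paths on small random graphs. Average clustering is the mean of local
coefficients over all nodes, counting degree<2 nodes as 0. Because the
"average degree" denominator is ambiguous in proteome studies, both
conventions are reported: 2|E|/|V| over graph nodes and 2|E|/N over a
caller-supplied total protein count. Centrality ranking breaks ties by
degree then id; proteins without disorder data are annotated as absent.

## Built-in stand-in predictors

These exist so the pipeline runs with no external tools; they are simple,
deterministic scorers, not reimplementations of the published predictors
whose files the I/O layer imports.

*Coiled-coil*: a sliding window (default 21 residues) scored over all 7
heptad register offsets; the score is the geometric mean of
position-weighted residue propensities from a small shipped table
(L/M/I/V favoured at core positions a/d, E/K/Q/R at flanks e/g,
G/P penalized); each residue takes the maximum score over covering
placements and is called coil at score ≥1.0. The table is chosen so an
idealized leucine zipper scores high and poly-G scores low; a brute-force
window×register enumeration is the test oracle.

*Disorder*: the classical charge–hydropathy discriminant
`2.785·⟨H⟩ − |⟨q⟩| − 1.151` on Kyte–Doolittle hydropathy rescaled to
[0,1], disordered iff negative; whole-sequence mode by default (the mean
is permutation-invariant), windowed mode optional.

## Synthetic cohorts

The generator emulates the statistical anatomy the pipeline measures,
with exact ground truth:

* **Lengths**: log-normal, default mean 796 residues with log-sd 0.8
  (heavy right tail; a control-like set uses mean 599). The log-normal
  shape reproduces the qualitative length distribution (mode near 500,
  long tail beyond 1000) of centrosome-scale protein sets.
* **Composition**: five segment types — globular, disordered loop,
  disordered helical, coil-and-disordered, coil-and-ordered — with
  residue fractions derived from target joint probabilities (defaults
  P(d)=0.57, P(c∧d)=0.124, P(c∧¬d)=0.007, P(d∧H)=0.30, so globular
  = 0.423, matching the published fraction of neither-disordered-nor-coil
  residues). Coil and disordered-helical segments are helical; globular
  segments draw H/E/C at (0.504, 0.165, 0.331), which puts the pooled
  helix/strand fractions near 52%/7%.
* **Heterogeneity**: each protein's dual (coil-and-disordered) content is
  drawn from a Gamma law with the pooled target as mean and shape 2.6 —
  solved so ~15% of proteins exceed 20% dual coverage, the published
  census — and laid down as coil-stretch-sized contiguous blocks. The
  remaining composition comes from a Dirichlet (concentration 8× the
  fractions) with exact per-protein residue budgets split into blocks of
  each type's characteristic length and shuffled; pinning budgets removes
  the length-biased truncation bias a naive iid segment stream has at
  protein boundaries.
* **Sequences** are composed per segment type (heptad repeats for coils,
  disorder-promoting residues for disordered segments, mixed composition
  for globular), but tracks are emitted from the generating labels, so
  statistics tests are independent of predictor quality. Running the
  built-in predictors on these sequences is a separate, harder exercise.
* **Template hits**: at most one primary hit per ordered run (length ≥40;
  rate 0.64, covering 85–100% of the run) and per long disordered run
  (≥60; rate 0.09, covering 50–80%), rates solved from the design targets
  of 57.2% modeled in ordered and 5.4% in disordered regions so ideal
  selection models ≈27.6% of residues overall. Identities come from the
  bimodal mixture (low peak 0.25±0.03, high 0.92±0.025, weights 99:174).
  Primary hits are span-disjoint by construction, so the ideal modeled
  fraction recorded in the ground-truth ledger is exactly their summed
  span; nested lower-identity decoy hits (rate 0.15) exercise the overlap
  rule without changing it.
* **Networks**: exact node/edge counts (defaults 167/354) under a uniform
  or preferential-attachment model.

All randomness flows from the single spec seed through
`numpy.random.SeedSequence` child streams (stream 0: proteins, 1: hits,
2: network); identical seeds give bit-identical cohorts.

What passing on synthetic data shows — and what it does not: recovery
tests demonstrate that the statistics, selection and accounting code is
unbiased and correctly seeded on data whose generating process matches
its assumptions. They do not validate the external predictors, the
homology search, or the biological claims; real predictor tracks have
autocorrelation structure, threshold artefacts and length biases the
generator does not attempt to mimic.

## Problem sizes and tolerances

Cohort-level tests use 500 proteins (~4·10⁵ residues), the scale of the
original study set, and compare recovered fractions to targets within 3
binomial standard errors computed at the protein level
(√(p(1−p)/n_proteins)) — residues within a protein are correlated, so
residue-level SEs would be dishonestly tight. Decision-rule oracles run
on 1000 random annotation layouts (segmentation), 500 random hit sets
(greedy selection) and 200 random graphs of ≤8 nodes (betweenness,
exhaustive path enumeration). The full suite completes in a few seconds
on one CPU.

Two tests check the deposited study/control sequence sets (mean longest-
isoform lengths 796 and 599, 361 and 500 genes). Those FASTA files are
not redistributable with the package; the tests look for
`data/table_s2.fasta` and `data/table_s3.fasta` and fail in their
absence. The generator's length defaults target the same means, as its
own design condition, not as a substitute for the real files.

## Known limitations

* The stand-in predictors are intentionally crude; their boolean calls
  should never be compared quantitatively with DISOPRED2/NCOIL-class
  output.
* The bootstrap treats proteins as exchangeable; gene-family structure or
  shared domains between proteins are not modeled.
* `identical_residues = round(identity × span)` is an approximation when
  hit tables lack explicit counts; ties at the rounding boundary can
  reorder the greedy pass relative to a tool that reports exact counts.
* The synthetic network model is degree-structure only; it does not
  emulate the biological clustering (complexes) of real interactomes, so
  clustering-coefficient values on synthetic graphs are near the random
  expectation.
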