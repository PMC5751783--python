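# Methods

## The descriptor

A molecule with atoms {1..n} contributes one point per unordered pair of
carbon/nitrogen atoms: `(δ₁, δ₂, d)` with δ the isotropic chemical shifts in
PPM and `d` the Euclidean interatomic distance in Å from the 3D coordinates
as given (geometry optimization is upstream of this package).  Hydrogens and
heteroatoms other than C/N never enter the descriptor.  Shifts follow the
convention of positive carbon and negative nitrogen values; a provider
emitting positive ¹⁵N shifts must be converted upstream.

The space is tessellated per pair class (CC, CN, NN) into disjoint bin-id
blocks, because the two shift axes have different windows and widths and a
mixed grid would create meaningless cells.  Orientation is canonicalized —
smaller shift on axis 1 for same-element pairs, carbon on axis 1 for CN — so
the fingerprint is independent of atom enumeration order, and it is exactly
invariant under rigid motion because only shifts and pairwise distances are
used.

### Binning parameters

| parameter | default | note |
|---|---|---|
| carbon window | −4 … +204 PPM | width 208, midpoint 100 |
| nitrogen window | −356 … −11 PPM | width 345, midpoint −183.5 |
| carbon bin width w_C | 8 PPM | divides the carbon window into exactly 26 bins; the window-commensurate choice at desk scale |
| N:C bin-width ratio | 2.5 | w_N = 20 PPM → 18 nitrogen bins, the last truncated at −11 |
| distance window | 1 – 20 Å, 1 Å bins | 1 Å matches the precision at which ring–nitrogen features are conventionally quoted (e.g. "7–8 Å") |
| occupancy | binary | see below |
| scaling | minmax | see below |

Shift-axis indices follow `floor((δ − lo)/w)` with the upper window edge
assigned to the last bin; values outside a window cause the pair to be
skipped (and counted), so in count mode `Σ occupancies + skipped = #pairs`.

### Occupancy and scaling

Two choices here were genuinely open and were settled by experiment on the
synthetic recovery benchmark:

- **Occupancy is binary by default** (a bin is present or absent), with
  `count` mode available.  Counts preserve the multiplicity of symmetric
  features, but they make the activation of the same chemical feature vary
  with molecular context (a compound realizing a feature once scores a
  fraction of one realizing it three times), which miscalibrates thresholded
  predictions on new compounds and lets dense ring self-pair bins dominate
  the importance ranking.  Presence/absence is the representation under
  which a feature means the same thing in every molecule.
- **Column scaling is min–max by default** (modeling-set range → [0, 1];
  constant columns → 0), with `zscore` and `none` available.  Z-scoring a
  sparse occupancy matrix gives a bin occupied by a single compound a ~5σ
  contrast — a ready-made memorization feature.  With tens of compounds and
  hundreds of bins this is fatal: members interpolate the training labels
  through rare bins, their holdout error rises from the first epoch, and
  best-holdout early stopping returns near-initialization weights.  Min–max
  keeps rare-bin leverage bounded.  The retained-bin set (bins nonzero in at
  least one modeling compound) and the scaling statistics are frozen from
  the modeling compounds and applied unchanged to external compounds.

## The classifier

An ensemble of 200 feed-forward networks, each with one trainable hidden
layer plus an output unit (a `hidden_layers: 2` switch exists; ambiguity
about whether "two layers" counts hidden layers or weight layers is resolved
in favor of weight layers).  Per member: a uniform-random holdout of
`round(0.25 · n)` modeling compounds (redrawn until the training partition
keeps ≥2 of each class), a hidden-unit count sampled from 3–16, and hidden /
output activations sampled independently from {identity, tanh}, emulating an
automated architecture search.  Identity outputs are clamped to [0, 1] for
prediction and aggregation only; training always uses the raw output.

Training is full-batch gradient descent on `E + λ Σ w²` with `E` the
sum-of-squares error, `λ = 10⁻⁴` (decay applies to weights, not biases),
learning rate 0.1 and at most 500 epochs.  Two numerical safeguards make the
fixed rate usable at any width:

1. the step applies the rate to the per-compound gradient (`η/n · ∇`), and
2. it is capped at 90% of the quadratic stability bound
   `1 / (2(λ_max(XᵀX) + λ))`, with `λ_max` from 30 power iterations.

Without the cap, a fixed rate diverges whenever the feature matrix is wide;
with it, descent is stable and the rate keeps its meaning on small problems.
A non-finite loss still triggers one restart at a tenth of the step before
raising a training failure.  Early stopping: when the holdout sum-of-squares
error fails to improve for 20 consecutive epochs, training stops and the
best-holdout weights are restored.  Small uniform weight initialization
(±`init_scale`/√fan-in) is deliberate: gradient descent from small weights
learns high-correlation directions first, which acts as implicit
regularization in the many-bins / few-compounds regime.

The ensemble score of a compound is the **median** of the 200 clamped member
outputs; class 1 (TdP risk) is predicted at score ≥ 0.5.  The tie goes to
the at-risk class because recall of truly torsadogenic compounds is the
quantity a safety screen must protect.  Evaluation reports both views: the
mean over members of each member's accuracy on its own training/holdout
partition (the natural summary of a subsampling design) and the
ensemble-median confusion matrix, accuracy, sensitivity, ROC curve/AUC and
gain curves per set.  ROC is marked undefined for single-class sets.

## Sensitivity analysis and toxicophores

For member *m* with baseline training error `E₀`, the sensitivity of bin *b*
is `E_b / E₀` where `E_b` is the error after replacing column *b* with its
training-partition mean.  A column constant on the partition scores exactly
1 (the substitution is the identity); a zero baseline is replaced by machine
epsilon and the member flagged.  The implementation updates the first-layer
pre-activation by the exact rank-1 term the substitution induces rather than
re-running the full input product; a from-scratch recomputation is kept as a
test oracle.  Aggregate sensitivity is the mean ratio over members, bins are
ranked by it, and the significant set is the top 5% (at least 3), or a ratio
threshold when configured.  Because members that fit their training
partition almost perfectly have tiny `E₀`, aggregate ratios can be very
large; only the ranking is interpreted.

Significant bins are decoded to (pair class, shift windows, distance range)
and matched against the atom pairs of the labeled-active compounds; a match
re-encodes to the same bin id by construction.  When a matched atom belongs
to an aromatic ring (every ring bond flagged aromatic in the input file,
falling back to RDKit perception when the file carries no flags), the
reported anchor is the ring centroid — the arithmetic mean of the member
coordinates — and the distance is recomputed to that anchor, while the raw
atom–atom distance (which defined the bin) is retained.  Display distances
are rounded to 0.1 Å; machine output keeps full precision.  Features are
reported per bin; adjacent significant bins are not merged.

## The synthetic generator

The generator emulates the statistical shape of a small TdP panel, not its
chemistry: compounds are C/N point clouds uniform in a 6 Å-radius sphere
with a 1.2 Å minimum separation, plus one planar hexagonal "aromatic ring"
template (circumradius 1.39 Å) whose six carbons share one shift — as
symmetry-equivalent aromatic carbons do.  Shifts come from class palettes
inside the binning windows: aliphatic C 30±12, aromatic C 128±8, amine N
−326±8, aromatic N −120±25 PPM.  Bonds are the ring bonds plus a
nearest-neighbor spanning tree and exist only so ring perception and file
round-trips are exercised.

Activity is planted geometrically: an active compound's ring shift is drawn
inside the rule carbon interval (default 124–132 PPM, one carbon bin) and a
nitrogen with shift in the rule interval (−336…−316 PPM) is placed 7–8 Å
from a ring carbon; inactive compounds are rejection-sampled until no
(C, N) pair satisfies the rule, all intervals half-open.  Labels equal the
rule flag XOR a Bernoulli(ε) flip; roles split ≈55:38 model:external,
stratified by class, mirroring the proportions of a modeling panel with a
blind post-marketing validation set.  Default conditions: 60 compounds,
10–16 atoms each, 50% active, ε = 0.

What passing tests on this generator do **not** show: real shift prediction
error (shifts here are exact by construction), conformational flexibility
(one rigid geometry per compound), chemically valid valences, correlated
real-world confounders between activity and composition, or class overlap —
the planted rule is perfectly separable, which is what makes recovery a
sharp test of the machinery rather than a benchmark of expected real-data
accuracy.  On real panels of this size, generalization in the high-60s
percent range is the realistic regime.

## The recovery experiment

`recovery_harness` runs generate → fingerprint → feature matrix → 200-member
ensemble → evaluation → sensitivity ranking → toxicophore mapping, deriving
stage seeds from one master seed via `SeedSequence([seed, stage])` (stage 0
generates, stage 1 trains).  Problem sizes — 60 compounds, 200 members,
three seeds with the median reported in the acceptance script — were chosen
to make the experiment decisive while keeping a full run in tens of seconds
on one CPU.  Under the default conditions the planted bin ranks first among
~600 retained bins, external sensitivity is 1.0, and external accuracy is
typically 0.83–0.96 across seeds.

## Known limitations

- No NMR shift prediction is included; real use requires an external
  predictor and the method inherits its errors.  The naive rule provider is
  a deterministic class-center lookup for fixtures only.
- One conformer per compound; flexible molecules whose relevant feature
  appears only in some conformers will be under-described.
- Bins are hard boxes: a feature straddling a bin edge splits its support.
  No soft binning or adjacent-bin merging is applied by default.
- The sensitivity aggregate is a mean of ratios with heavy-tailed member
  contributions; ranks are stable but magnitudes are not comparable across
  datasets.
- Class imbalance is not reweighted (the modeling design assumes a roughly
  balanced panel).
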