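# Methods

## The modelling problem

A pharmaceutical assay panel measures a set of physico-chemical endpoints
— here ten: logD at neutral (LOD) and acidic (LOA) pH, membrane affinity
(LOM), human serum albumin binding (LOH), melting point (LMP), and five
aqueous-solubility assays (LOO, LOP, LON, LOX, LOQ) of which three (LON,
LOX, LOQ) are *helper tasks*: endpoints kept in the joint training only
because they are correlated with solubility endpoints of interest, while
their own accuracy is not a deliverable.  Every compound has labels for
only a subset of tasks, so the label matrix is sparse; tasks differ in
size by an order of magnitude.

## Preprocessing model

Raw records are per-measurement `(compound, endpoint, value, qualifier,
date)` tuples in assay units.  The pipeline applies, in order:

1. **Qualifier resolution**, per measurement, before any averaging:
   `< v → v/2`, `> v → 2v`.  The ordering matters — averaging first and
   adjusting after is not equivalent — and per-measurement adjustment is
   the natural reading since the qualifier is a property of the single
   measurement.  This is a crude stand-in for censored-data likelihoods,
   deliberately so; no censoring model is fitted.
2. **Structure standardization**: keep the largest fragment, neutralize by
   (de)protonation, clear stereo, optionally canonicalize the tautomer
   (RDKit's canonical-tautomer routine; switchable because tautomer
   algorithms differ between toolkits).  Compound identity is the
   canonical standardized structure, not the vendor ID.
3. **Replicate averaging** on the raw (assay-unit) scale, then the
   endpoint transform.  Averaging raw-then-transforming was chosen over
   transforming-then-averaging; for log endpoints the two differ by the
   Jensen gap, and the raw-scale mean is what an assay report calls "the
   final experimental value".  Records whose adjusted value is
   non-positive under a log transform are dropped and counted, not
   clamped: the log is undefined and inventing a floor would bias small
   solubilities.
4. **Endpoint transforms**: solubilities mg/L → log10 mol/L (requires the
   molecular weight), LOM/LOH log10, logD and melting point unchanged.
5. **Per-task standard scaling** to zero mean, unit variance, so melting
   points (tens to hundreds of °C) and log-unit endpoints contribute
   comparably to a joint loss.  Scalers are fitted on training cells only
   and reused for validation/test — refitted inside every CV fold — to
   avoid leakage.

## Models

**Dense networks.** Input: ECFC6 count fingerprints folded to 1024 or
2048 counts by modulo reduction of 32-bit circular identifiers.  The
fingerprint enumeration emits exactly one identifier per atom per radius
0–3 (so folding conserves the total count, `4 × n_atoms`); this
convention keeps the representation's bookkeeping exactly testable.
Architecture: four ReLU hidden layers 2000/1000/500/100 with dropout
0.5/0.5/0.25/0, He-initialized weights, zero hidden biases, output bias
−1 (an empirically motivated prior that standardized targets sit below
zero more often than above at initialization).  Because count
fingerprints are sparse, input dropout would mostly delete zeros; instead
each input element is *replaced*, with probability p (default 0.01), by a
synthetic count `|round(N(0, 3))|`, and a tanh squashes counts to (−1, 1]
afterwards.  Replacement is per element: the point of the scheme is to
"drop in" individual chemical features, which a per-vector replacement
would not do.  At inference p = 0 and only the tanh remains.

**Graph convolutional networks.** Input: heavy-atom graphs with 75 binary
atom features.  The defining publication for this architecture family
defers the exact feature list to an appendix; the layout adopted here is
the convention of the reference implementation it cites, and is part of
this package's contract: element one-hot over 43 symbols + "other" (44),
heavy-atom degree 0–10 (11), implicit valence 0–6 (7), formal charge (1),
radical electrons (1), hybridization SP/SP2/SP3/SP3D/SP3D2 (5), aromatic
flag (1), total H count 0–4 (5) — total 75.  Two convolutions
`h'_v = ReLU(W_self h_v + W_nb Σ_{u∈N(v)} h_u + b)` of width 128, a
per-atom dense layer to 256, then readout: mean over atoms ⊕ max over
atoms, tanh, giving a 512-dim embedding; one linear unit per task.  Bond
types are not distinguished and hydrogens are implicit.  A single
(W_self, W_nb) pair per layer is the default — the architecture is
deliberately simple; degree-specific neighbour weights, a neighbourhood
max-pool and batch normalization (present in some reference
implementations, unreported in the runs this design follows) exist behind
config flags and are never silently on.

Every readout and convolution is invariant to atom numbering; this is
asserted to 1e-5 over random renumberings as a standing test.

**Numerical core.** Both models run on a minimal reverse-mode autodiff
engine over float64 NumPy arrays (elementwise ops with broadcasting,
matmul, constant-sparse matmul for neighbour sums, segment mean/max for
readout).  Gradients at segment-max ties are split evenly among tied
rows (a valid subgradient preserving gradient mass); ReLU uses the
zero subgradient at 0.  Backprop is property-tested against central
finite differences (relative tolerance 1e-4 at network level, 1e-6 at op
level).

## Training

Adam (default moments), learning rate 0.001, batch size 128, 40 epochs,
exponential learning-rate decay every 1000 steps; the decay factor is
unpublished in the sources this design follows, so 0.95 is a labelled
config default, as are the dense net's weight decay (1e-5).  Minibatches
sample compounds uniformly; the masked loss handles whatever task mix a
batch contains.  The loss is

`L = Σ_{t present} w_t · L_t`,  `L_t = mean over labeled cells of (ŷ−y)²`,

with *simple* weights `1/N` (N = tasks with ≥1 label in the batch) or
*balanced* weights `w_t ∝ 1/n_t`.  For balanced weighting `n_t` defaults
to the **global training-set task size** — the reading under which large
tasks are systematically down-weighted, which matches the observed
behaviour such weighting is meant to produce — while a per-minibatch
variant is available behind `per_minibatch=True` since the narrower
reading is also defensible.  Tasks absent from a batch contribute
nothing; gradients at unlabeled cells are exactly zero (asserted).
Training is bit-reproducible for a fixed seed on one device.  There is no
early stopping: the epoch count is fixed by design.

## Validation splits

*Leave-cluster-out*: k-means (k-means++ init, fixed seed) on raw count
fingerprints, K = 10.  Clusters lacking a labeled compound of some task
are merged — smallest deficient cluster first — into the nearest (by
centroid Euclidean distance) *larger* cluster, repeated until every fold
covers every task; if no larger cluster exists the nearest of any size is
used.  Which fingerprint variant (1024/2048, counts/binary) feeds the
clustering is a config choice; the default is 2048-count.  One fold may
be designated as the test set.  *Matched random*: a random partition with
the identical fold-size multiset, repaired by coverage-preserving swaps.
*Time splits*: each labeled cell is dated by the **latest** replicate
date (conservative: keeps late information out of training) and assigned
train/test against a cutoff; the strict variant removes from all training
sets any compound occurring in any task's test set.  Tasks without dates
(LOA in the synthetic panel) are split randomly at the overall test
fraction.

## Metrics and the GSE audit

r² is the coefficient of determination `1 − SS_res/SS_tot` — not squared
Pearson — and can be negative; Spearman uses average ranks for ties.
Per-fold values are averaged (mean ± sd); folds are never pooled.
Helper tasks are trained but excluded from headline averages.

The general solubility equation
`logSw = −0.01(LMP − 25) − log Kow + 0.5` (logSw in log10 mol/L, LMP in
°C) is used as a physics consistency audit: correlate
`GSE(predicted LMP, predicted logD)` with predicted logS on a held-out
set (logD stands in for log Kow — an approximation, inherited from the
workflow this mirrors), compare with the same correlation on measured
values, and with `corr(−predicted logD, predicted logS)` alone.  The gap
between the full-GSE correlation and the logD-only correlation measures
how much melting-point information the model actually uses.

## Synthetic data generator

The generator emulates the *structure* of a corporate ADMET panel, not
its value distributions.  Defaults (all chosen once, on field-realism
grounds):

- **Molecules**: fragment grammar (13 aryl/heteroaryl/alicyclic cores, 20
  substituents) assembled by seeded random attachment at H-bearing atoms;
  heavy atoms ~ N(22, 6) clipped to [8, 40] — a drug-like unimodal size
  distribution; all structures valence-valid and unique.
- **Ground truths** (model scale), driven by four cheap descriptors
  (carbon count, N+O count, ring count, H-bond donors):
  `logKow* = 0.25·#C − 0.55·#(N,O) + ε(0.30)` (Crippen-like atomic
  contributions), `LMP* = 60 + 22·#rings + 18·#donors + ε(15)` °C,
  `logS* = −0.01(LMP*−25) − logKow* + 0.5 + ε(0.30)` — exactly on the GSE
  surface at zero noise; LOD/LOA are offsets of logKow* (−0.3, −1.2) with
  ε(0.25); LOM/LOH affine in logKow* (0.7·+1.0, 0.5·+0.8, ε 0.30); the
  helper solubilities are logS* re-noised (ε 0.30–0.35).  A
  `noise_scale` multiplier scales every ε (0 gives the exact GSE
  fixture); `independent_solubility` replaces logS* by N(−3, 1.5) to
  create the null case for the audit.
- **Records**: task sizes are fixed fractions of the panel (LOA 0.90 the
  largest, LOP 0.10 the small task of interest); 15% of cells carry a
  replicate (jitter 0.05 log units, 2 °C for LMP); 5% are
  qualifier-censored as `("<", 2v)` or `(">", v/2)` so the preprocessing
  rule approximately recovers v — making the qualifier pipeline testable
  for bias; dates uniform over 2010-01-01..2016-06-30 with 2014-06-30 the
  canonical cutoff; LOA is undated.

Because the truths are linear in descriptors, a linear regression on the
true descriptors is a closed-form performance oracle: it upper-bounds any
structure-based model, so the end-to-end recovery check (held-out
R² ≥ 0.6 on LOD for the multitask GCN at the 2000-compound default
conditions) does not hinge on network capacity.  What passing these
tests does *not* show: real assay noise is not Gaussian or homoscedastic,
real endpoints are not linear in four descriptors, real chemical series
form far tighter clusters than fragment-grammar molecules, and real
panels are 10–100× larger.  The generator validates the machinery, not
transferability to proprietary data.

## Problem sizes and runtime choices

The standing test suite trains small networks (reduced widths) for the
convergence, replay and determinism checks, and the full-architecture
multitask GCN once on the 2000-compound default study; that run takes a
few minutes on one CPU.  The package's default hyperparameters are never
reduced — only problem sizes used in tests are.

## Known limitations

- No censored-data likelihoods, assay QC or curve fitting.
- No scaffold splits and no temporal cross-validation (a single temporal
  cutoff only).
- No hyperparameter search harness; defaults labelled as such where the
  sources left values unreported.
- Checkpoints store plain arrays; no versioned migration.
- The autodiff core supports exactly the ops these architectures need;
  it is not a general-purpose framework.
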