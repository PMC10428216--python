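# Methods

## The analysis model

The package operationalizes one idea: the conformational flexibility of a
kinase's activation segment encodes its activity state. Three measurements
support it.

**Per-residue RMSF.** For a trajectory with frames *t* and atom positions
x_i(t), frames after an equilibration discard are rigid-body superposed onto
a mean structure and

RMSF_i = sqrt( ⟨ ‖x_i(t) − ⟨x_i⟩‖² ⟩_t )

per atom; a residue's RMSF is the RMS over its selected atoms. "Backbone"
means the conventional N, CA, C, O set. The fitting protocol is: fit all
retained frames to the first frame, then iterate (fit onto the mean →
recompute the mean) until the mean structure moves by < 1e-9 Å (at most 30
passes). Iterating to the fixed point — rather than a fixed number of
refinement passes — makes the profile independent of the arbitrary starting
reference; the test suite asserts that one further iteration changes the
per-residue profile by < 1e-6 Å. Superposition uses the Kabsch SVD
construction with the determinant correction, so the rotation is always
proper; masks with fewer than 3 atoms or collinear geometry are rejected.
Exactly identical frames short-circuit to the exact identity transform so a
rigid trajectory yields an RMSF of exactly zero rather than SVD round-off.
All internal units are Å.

**The one-rule classifier.** Given the kinases × alignment-columns matrix
X (RMSF values) and binary labels y, the model is a depth-one decision
stump: a single (column *j*, threshold θ, orientation) rule. Fitting
exhaustively scores every column at every midpoint between consecutive
distinct sorted values by weighted Gini impurity and keeps the minimizer.
Determinism conventions (matched exactly by the brute-force oracle the
tests run): impurity ties break to the lower column position, then the
lower threshold; the below-threshold class is the side's majority with
exact ties going to "active". The constraint to one rule is deliberate —
interpretability over capacity — and evaluation is by repeated random
holdout: train fraction 0.7 (30 of 43 rows at the default panel size), 100
random splits, balanced accuracy = (sensitivity + specificity)/2 on the
held-out rows, aggregated as mean ± population sd. Splits are simple random
draws, not stratified; a draw leaving a single class on either side is
redrawn (the validation side needs both classes for balanced accuracy to be
defined; redraws are bounded, then an error). The ablation cascade removes
the modal selected column of a full evaluation and repeats, exposing which
columns carry redundant copies of the signal. The lasso corroboration is
L1-penalized logistic regression on internally standardized columns
(scikit-learn, liblinear); as the penalty vanishes it converges to the
unpenalized logistic fit (pinned in a test against an independent
optimizer).

**Pocket networks.** A pocket tracker emits per-frame volumes and
merge/split events between pocket pairs. Events are counted exactly as
recorded into the (possibly asymmetric) merge matrix α and split matrix β;
the connection matrix is

γ = ½ (sym α + sym β),  sym M = ½ (M + Mᵀ),

symmetric with zero diagonal by construction, and total weight is conserved:
sum γ = ½ (sum α + sum β). γ is left as raw counts by default; a per-ns
normalization is available for comparing runs of unequal length. A pocket's
time-averaged volume is the mean over **all** frames with undetected frames
counted as 0 Å³ — averaging only detected frames would leave a never-seen
pocket undefined instead of 0, and pocket absence is itself signal. The
scalar fed to group comparison for "connections" is the per-system
per-pocket row sum of γ (the row-wise reduction of the connection
distribution); the pooled off-diagonal row entries are also exposed for
histogramming.

**Group comparison.** Welch's unequal-variance t-test,
t = (x̄ − ȳ)/√(s²_x/n_x + s²_y/n_y), with Welch–Satterthwaite degrees of
freedom and two-sided p-values from Student's t (delegated to scipy; the
suite pins it to an independent quadrature oracle at 1e-10 and to the exact
pooled-Student reduction at equal n and variance). Sample variances use the
n−1 denominator. Raw p-values are reported per pocket with a significance
flag at α = 0.05; no multiple-testing correction by default (a Bonferroni
flag exists). A pocket missing one class is reported untestable, never
silently dropped.

**Conformational clustering.** The distance between frames is the RMSD over
the activation-loop selection after superposing one frame onto the other
over that same selection: segment fitting isolates loop conformation from
global domain motion (a whole-molecule fit is available via `fit_mask` /
`--fit-on whole`). Clustering is k-medoids by Voronoi iteration (alternate
nearest-medoid assignment and within-cluster medoid update to a fixed
point), k = 10 by default, with greedy farthest-point seeding from a
seed-chosen first medoid. Ties break to the lower index everywhere, making
runs fully deterministic; the objective (sum of member-to-medoid distances)
is asserted non-increasing at every iteration. The transition graph counts
undirected consecutive-frame cluster changes as edge weights, stores
cluster cardinality and optional mean activity per node, and satisfies
(total edge weight) + (persistence count) = n − 1. Distances are
unweighted (no atomic masses). Note RMSD-after-superposition need not obey
the triangle inequality; only symmetry, non-negativity and zero diagonal
are required of the matrix.

## Residue-to-column mapping

The fluctuation matrix is defined over alignment columns, not residue
numbers. The k-th non-gap character of a kinase's aligned sequence
corresponds to its k-th residue id, and the panel retains exactly the
columns ungapped in **every** sequence — the strictest rule that guarantees
a complete matrix. A mismatch between a kinase's ungapped length and its
residue list is an error reporting both lengths; a retained column that
cannot be resolved in some kinase's RMSF profile aborts assembly with the
full failure list. Activity labels are active ⇔ mean activity probability
≥ 0.5, the symmetric cut.

## Synthetic generators: what they emulate and what they do not

`gen_trajectory` draws every atom i.i.d. Gaussian around its mean with a
per-residue σ, giving the closed form RMSF = σ√3 that anchors the oracle
tests (empirically, the superposition fit absorbs 6 rigid-body degrees of
freedom, biasing the RMSF low by a factor ≈ √(1 − 6/(3N)) for N atoms —
about 0.8 % at the 120-atom default, well inside the 2 % test band). It has
no bonded structure, no anisotropy, and no temporal correlation, so it
validates the estimator's arithmetic, not force-field realism.

`gen_fluctuation_panel` plants the study regime as its defaults: 43 kinases
(20 active / 23 inactive), 223 columns, one signal column with class means
0.6 Å (active) vs 1.3 Å (inactive) and within-class sd 0.18 Å, background
columns at 1.0 ± 0.25 Å, and a 3-column block correlated with the signal at
ρ = 0.95, mimicking how the residues just downstream of the DFG motif
co-fluctuate with the key DFG+3 lysine/arginine. All draws are truncated at
0 (an RMSF cannot be negative); correlated columns are built from the
standardized signal, rescaled to background spread and clipped at 0. Class
means/sds were chosen once to put the planted separation at ≈ 3.9
within-class sds — strong enough that the rule is recoverable, weak enough
that holdout accuracy stays below the ceiling. Real kinome panels have
row-wise correlation structure, alignment noise and label uncertainty that
these panels do not; passing tests demonstrate the estimator recovers a
planted rule under the stated noise, not that any real kinome obeys it.

`gen_pocket_events` gives each pocket a per-frame Bernoulli presence, a
lognormal volume when present (log-space parameters; defaults around the
~550 Å³ scale of the ATP site), and independent Poisson merge and split
events per ordered pair at a known link rate (default 0.005/frame/pair over
5000 frames at 100 ps spacing). Merge and split streams are generated
independently since α and β are counted separately before averaging. Real
pocket dynamics are bursty and volume-coupled; the generator's independence
assumptions are what make the γ and rate-recovery oracles exact.

All three generators are bit-reproducible from their spec's seed.

## Numerical and design choices

- Gini impurity (not entropy) as the stump criterion, midpoint thresholds,
  and the tie-break order above: these are declared conventions pinned by
  the oracle-equality tests.
- The population sd (ddof = 0) is reported over evaluation repeats.
- Degenerate inputs error loudly: single-class fits, all-constant matrices,
  empty selections, discards leaving < 2 frames, distance matrices that are
  asymmetric or have nonzero diagonals, unknown pocket names (with frame
  index).
- k-medoids uses Voronoi iteration, not PAM swap search; the documented
  guarantee is per-iteration objective monotonicity and determinism, not
  global optimality.
- The end-to-end driver (`kinoflex.pipeline.run_pipeline`) writes only
  sorted-key JSON and pandas CSV, which makes the two-runs-byte-identical
  determinism check meaningful.

## Problem sizes

The test suite and `scripts/acceptance.py` run at desk scale, chosen as the
smallest sizes at which each property is sharp: 100 panels × 100 holdout
repeats for signal recovery; 200 random instances for stump–oracle
equality; 50 label shuffles for the permutation null; 20 panel seeds for
the ablation pattern; 10 000-frame trajectories for the σ√3 closed form;
700 null Welch tests for type-I calibration; 30-frame two-bundle instances
for cluster recovery. The headline numbers of the original kinome study
(e.g. a ~73 % balanced accuracy and a 0.9 Å threshold at the DFG+3 residue)
are functions of microsecond-scale MD on 43 kinases and cannot be
recomputed from synthetic panels; what the acceptance run establishes is
that every algorithmic component is exact where exactness is defined and
calibrated where the check is statistical.

## Known limitations

- No mass-weighting, periodic-boundary unwrapping, or compressed binary
  trajectory formats; multi-model PDB and a flat CSV coordinate table are
  the supported trajectory inputs.
- The MSA is consumed, never computed; running an aligner is out of scope.
- Pocket *detection* is out of scope; the package consumes event logs.
- The activity-probability series is an external classifier's output,
  consumed as given.
- t-SNE-style projections are visualization conveniences left to standard
  tooling and not wrapped here.
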