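# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `screenvalid`, and what its synthetic-data generators do and do not
emulate.

## Library curation (`chem_props`)

Standardization applies four auditable rules in order: unparseable SMILES
are dropped (`parse_error`); multi-component structures — salts and
fragmented records — are dropped whole rather than stripped to a largest
fragment (`multi_component`), which keeps the exclusion rule auditable;
carbon-free species are dropped as the operational proxy for "inorganic"
(`inorganic`); and duplicates are resolved by canonical-SMILES equality
after standardization (`duplicate`), first occurrence kept. Survivors carry
their canonical SMILES, making the operation idempotent. Every removal is
logged as `(id, reason)`.

Descriptors are RDKit's: average-mass molecular weight, Crippen
fragment-additive logP, and Lipinski-style H-bond counts — donors are N/O
heavy atoms bearing ≥ 1 hydrogen, acceptors are all N and O atoms. Screening
engines differ in their perception schemes, so absolute parity with any
particular engine's counts is not expected; what matters for decoy matching
is that one fixed, documented scheme is applied uniformly to actives and
pool. Before computing descriptors the molecule is re-canonicalized so that
atom-ordering-dependent float summation (logP is an atom-wise sum) cannot
make equal structures yield unequal vectors. Tautomer/charge normalization,
stereo-aware deduplication and 3D energy minimization are out of scope;
conformers are accepted as supplied.

## Decoy construction (`decoy_builder`)

Pool members whose canonical structure equals any active's are removed
first — exclusion is structural, not id-based, so renamed copies of actives
are caught. Candidates for each active are the remaining pool members whose
four property deltas all lie inside the matching windows; they are ordered
by Euclidean distance in z-score space (per-property normalization by the
filtered pool's SD; constant columns get unit scale) with lexicographic id
as the deterministic tie-break. Selection is greedy without replacement,
round-robin over actives in input order, until `⌈ratio·|actives|⌉` decoys
are chosen or every queue is exhausted; exhaustion yields a shortfall
warning, not an error.

Defaults: windows ±25 Da (MW), ±1.0 (logP), ±1 (HBD), ±2 (HBA);
these are artifact defaults — the protocol this mirrors leaves the
tolerances to the builder — and all are configurable. The ratio presets
1.54 and 1.56 correspond to the two reference validation sets (2080 decoys
for 1352 actives; 2162 for 1389). Round-robin prevents early actives from
monopolizing the pool; enlarging all windows can only enlarge the candidate
union, so the selected count is monotone in window size. Topological
dissimilarity filtering of decoys (a fingerprint criterion some benchmarks
add) is deliberately not applied: matching is on the four named properties
only. The per-active (rather than pooled-distribution) matching choice
follows standard benchmark practice.

`audit_decoy_set` reports per-property means/SDs for both sets, max
absolute matching deltas, and the active-overlap count (invariantly 0).

## Ranking metrics (`screen_eval`)

The merged library is stably sorted by descending score; runs of equal
scores are recorded as tie groups.

- Cutoff counts use nearest-integer rounding with halves up,
  `n_f = ⌊f·N + 0.5⌋`, clamped to `[1, N]`. This is the only rounding rule
  consistent with both reference cutoffs (34 of 3432 and 36 of 3551 at 1%)
  *and* all six reference enrichment factors derived from the printed
  active counts — e.g. 117/172 actives at 5% of 3432 gives EF 1.73 only if
  171.6 rounds to 172.
- `EF_f = (a_f/n_f)/(A/N)` is kept at full precision internally and rounded
  to 2 decimals in reports.
- ROC-AUC uses the rank-sum identity with mid-ranks for ties; it equals
  trapezoidal ROC integration and the normalized Mann–Whitney statistic
  (both verified against independent oracles in the tests).
- RIE/BEDROC follow the Truchon–Bayly formulas with mid-rank tie handling
  (actives in a tie group take the group's average rank). α defaults to 20,
  the standard early-recognition choice, and is exposed everywhere. BEDROC
  is clamped to [0, 1] to absorb ~1e-15 overshoot at the perfect-screen
  boundary. A tie group straddling a cutoff boundary is resolved by stable
  sort order and reported via `boundary_tie_warning`.
- Screens that are empty or single-label are flagged degenerate and every
  metric refuses them with `degenerate_labels`.

One producer (`screen_library`) emits `-inf` sentinel scores for molecules
with no complete mapping; all metrics operate on ranks, so the sentinel
simply pins those molecules to the bottom.

## Pharmacophore fit (`pharmacophore`)

A model is 3–5 typed feature spheres (H/D/A/R) with centers, tolerance
radii (default 1.6 Å) and weights (default 1.0). Ligand perception places
D points at N/O atoms bearing hydrogens, A at all N/O atoms, R at
aromatic-ring centroids, and H at centroids of connected groups of ≥ 3
non-aromatic carbons (aromatic carbons are covered by R, so benzene yields
exactly one R point and no H).

Mapping enumerates every injective kind-compatible assignment of model
features to cloud points (model size ≤ 5 keeps this exhaustive), rigidly
superposes the assigned points onto the feature centers by Kabsch
least-squares (SVD with determinant correction, so only proper rotations),
and computes per-feature residual distances `d_i`. The screening rule
admits no omitted features: only complete assignments are considered.
Under `require_all` (default) an assignment is accepted only when every
`d_i ≤ t_i`; the fit value is

    fit = Σ_i w_i · max(0, 1 − (d_i/t_i)²),

a continuous, bounded score that is maximal (Σw) at perfect overlay and
invariant under rigid motions of the cloud. The quadratic-penalty form is
this package's own stand-in for proprietary fit functions, chosen for those
properties; no reference number depends on it. Per-feature contributions
are floored at zero so fit ≥ 0 also when tolerance acceptance is relaxed.
Conformer generation is out of scope: the scorer takes supplied conformers
(best fit over a molecule's clouds wins).

## Synthetic data (`synthetic_data`)

- **Score lists**: equal-variance binormal model — active scores
  `N(μ_a, σ²)`, decoy scores `N(μ_d, σ²)` — chosen for its closed-form
  expected AUC `Φ((μ_a−μ_d)/(σ√2))`, which anchors parameter-recovery
  tests. Real screening score distributions are neither normal nor
  equal-variance; the model claims nothing about them.
- **Compound pools**: property marginals default to drug-like ranges
  (MW ~ N(350, 80) truncated at 60 Da, logP ~ N(2.5, 1.5), HBD categorical
  on 0–5, HBA on 0–10), drawn independently per property. Real libraries
  correlate these properties (heavier molecules carry more acceptors);
  independence is accepted for simplicity, so passing tests demonstrate
  correctness of the matching machinery, not realism of the joint
  distribution. SMILES come from a curated ~40-structure template bank
  sampled with replacement so records parse and standardize; property
  vectors are simulated, not recomputed from the templates.
- **Feature clouds**: model centers plus isotropic Gaussian jitter plus a
  Haar-random proper rotation and a uniform translation; an optional kind
  swap mutates one feature so complete mapping fails at small jitter. The
  planted-separation library (0.2 Å jitter for actives, 1.5 Å for decoys,
  tolerance 1.6 Å) is the fixture behind the end-to-end AUC > 0.9 check.

All generators are pure functions of (config, seed).

## Pipeline (`pipeline`, CLI)

Two scoring modes, recorded in the report: `scores` (external score table,
for screens ranked by an outside engine) and `pharmacophore` (built-in fit
scorer on a model plus cloud library). Curation and decoy building run
whenever actives + pool are configured. Every stage logs record counts
in/out; the report JSON carries a config hash and package version but no
timestamp, so identical config + seed reruns are byte-identical. Score
tables accept both the numeric label encoding (2 = active, 1 = decoy) and
the words. Exit codes: 0 ok, 2 config error, 3 stage failure.

## Problem sizes used in validation

The acceptance script evaluates the two reference screens at their real
sizes (3432 and 3551 molecules) — milliseconds of work. Test-suite
simulations use 200-seed Monte-Carlo batches at the reference set sizes for
AUC recovery, 10⁴ small random screens for BEDROC bounds, a 3000-molecule
pool for decoy invariants and a 120-molecule cloud library for the
end-to-end run; these sizes give stable statistics while keeping the whole
suite fast.

## Known limitations

- Matching windows and the α parameter are conventions, not fitted values.
- The fit function is a documented stand-in; absolute fit values are not
  comparable to any proprietary engine's.
- Decoys are presumed inactive; no bioactivity check is possible here.
- Reference ROC-AUC/BEDROC values from full rank vectors cannot be
  recomputed without those vectors; the package instead verifies the
  metric implementations against closed forms, brute-force oracles and
  simulation (see the test suite).
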