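# Methods

## The model

`zincsite` treats zinc-binding-site prediction as a per-family binary
classification of candidate residue combinations. A *family* is the multiset
of liganding residue types (C2H2, C4, H3, ...); ten families of site size 2,
3 or 4 are supported, all drawn from the four residues (C, H, D, E) that
dominate high-affinity zinc coordination. The unit of prediction is the
whole candidate site: a combination of residues whose types match the
family, enumerated exhaustively in the query. This follows from the
chemistry — no residue binds zinc in isolation; only particular
combinations do.

Each family/modality pair gets its own Random Forest. Forests suit the
problem: features are few (7–9), heterogeneous in scale (residue counts,
kcal/mol, Angstroms) and interact non-linearly (e.g. gap patterns), and
forests need no feature scaling and give calibrated-enough vote fractions
to report as probabilities.

## Features

**Sequence** (site size k → k + 5 features, fixed order `gap_1..gap_{k-1},
hydrophobicity_w1/w3/w5, charge_w1/w3/w5`):

* *gaps* — residues strictly between consecutive binding residues; captures
  the spacer patterns characteristic of, e.g., zinc fingers.
* *windowed hydrophobicity* — mean Wimley–White value over windows of 1, 3
  and 5 residues centred on each binding residue. The interface scale
  (water → POPC interface, kcal/mol) is the default; the octanol scale is
  shipped as an alternative and any mapping can be supplied. Windows are
  clipped at the termini and the mean divides by the residues actually
  included (no phantom padding). Overlapping windows of nearby binding
  residues count shared residues once per window — the simplest reading of
  "average around the residues".
* *windowed charge* — mean per-window **count** of charged residues
  {D, E, R, H, K} (a count, not a density, so clipping can only lower it).

**Structure** (9 features): mean, max, min and *population* standard
deviation of all C(k,2) pairwise inter-Cα distances; the same four for
inter-Cβ distances; and the hydrophobic contrast at the Cβ centroid with
radius R = 4 Å. Population (ddof = 0) std is used because the C(k,2)
distances are the complete population, not a sample; for two-residue
families (one distance) it is 0 by definition.

The contrast descriptor is implemented as
`sum_i h_i · (2 d_i² − R²)/R²` over non-hydrogen atoms within R of the
probe centre, with per-element hydrophobicities h(C) = +1,
h(N) = h(O) = h(S) = −1, others 0 (both configurable). The quadratic weight
is −1 at the centre, +1 on the sphere surface and crosses zero at R/√2, so
the value is high exactly when hydrophilic atoms cluster at the centre and
carbon-rich packing surrounds them — the shell structure typical of metal
centres. The weight's exact functional form is this package's choice,
documented here because published contrast formulations vary; the
implementation preserves the defining qualitative contract (monotone in the
radial position of each atom, zero-centred), which is what the property
tests pin down. By default the atom cloud contains polymer atoms only;
waters are always excluded and other hetero atoms are opt-in
(`include_hetero`).

## Candidate enumeration

Positions are 0-based internally; all user-facing output is 1-based (or
chain:number for structures). Candidates are ordered lexicographically by
position tuple, making every downstream artefact reproducible. Sequence
enumeration bounds the first-to-last span at 200 residues by default —
combinatorially necessary on long sequences and far above any plausible
loop-spanning site. Structure enumeration keeps only combinations with all
pairwise inter-Cα distances ≤ 30 Å (more distant residues cannot coordinate
one ion) and never includes hetero/modified residues. Residues missing a Cβ
(glycine, or truncated side chains) get an idealized Cβ constructed from
backbone geometry, with a warning — none of the ten families' liganding
residues should need this, so it is purely defensive.

## Dataset construction

Positives come from a site catalogue (TSV); sequence sites split across
multiple chains are discarded, and structure sites are kept only when the
parent structure's resolution is strictly better than 2.0 Å ("better than"
read strictly; entries with missing resolution are excluded with a
warning). Negatives are family-matching combinations drawn from a pool of
non-binding sequences/structures: a pool member chosen uniformly, then a
combination within it chosen uniformly among those that do not equal any
catalogued site (exact position-set inequality — overlapping-but-different
combinations are legitimate negatives, since the procedure samples
combinations, not regions). Sampling redraws up to 1000 times per required
sample before declaring the pool exhausted, in which case a partial dataset
is returned with a warning and the achieved ratio recorded.

Negatives are drawn *distinct* by default. With a database-scale pool
duplicate draws essentially never happen; with a desk-scale pool they do,
and duplicated rows straddle any train/test split, letting the forest
memorize them (measured: null-regime MCC inflates to ~0.3). Distinct draws
restore the intended semantics of an effectively unbounded pool.

The combined table is balanced 1:1, shuffled under the run seed, and is a
pure function of (inputs, seed). Redundancy reduction consumes external
cluster assignments (e.g. CD-HIT) from a two-column TSV and keeps one
uniformly chosen representative per cluster; a toy greedy 3-mer-Jaccard
clusterer is included for tests and demos only — it is not a CD-HIT
replacement.

## Training protocol

Stratified 20:80 test–train split; stratified 5-fold cross-validation of
the training set over the 48-point grid (criterion ∈ {gini, entropy} ×
max depth ∈ {4, 6, 8, ∞} × trees ∈ {10, 100, 1000} × features per split ∈
{sqrt, log2}); selection by mean fold F1 with ties broken by first-best in
fixed enumeration order; final refit on the full training set. Stratification
is used for both the split and the folds because per-family datasets can be
small enough for unstratified folds to go single-class (which is treated as
an error, not silently scored). Metrics are recall, precision, F1 and MCC
computed from the closed-form confusion formulas; zero denominators yield 0
with an explicit `degenerate` flag. Accuracy is never reported. One run
seed governs the split, folds, subsampling and forest randomness and is
recorded in the model bundle, alongside the feature schema, chosen
hyper-parameters and a dataset hash; bundles refuse to load on
format/version/schema mismatch.

`learning_curve` fixes the forest hyper-parameters (default 100 trees,
gini, sqrt, unlimited depth) across stratified subsample fractions so the
curve isolates dataset-size effects.

## Prediction

Hits are candidates scoring at or above the reporting threshold
(default 0.5 — the decision boundary; configurable, with all probabilities
always present in the output). Overlapping hits of the same family are all
reported; no non-maximum suppression is applied, leaving merging policy to
the consumer. A proteome scan labels a sequence zinc-binding if any
family's model yields at least one hit, and reports the binding fraction.

## Synthetic data

The fixture generators exist so the whole pipeline runs and can be
calibrated offline. Their defaults define the study conditions used
throughout the tests and the acceptance script:

* **sequences** (length 120): positives plant one family arrangement with
  gaps ~ round(N(3, 1)) clipped at 0 and hydrophobic-biased flanks
  (probability 0.9 of replacing each ±2 neighbour with one of I/L/V/F/W/M);
  background sequences plant one arrangement with gaps ~ round(N(15, 4))
  and unbiased flanks. Context residues exclude C/H/D/E so each sequence
  holds exactly one family-matching combination, keeping enumeration
  counts and negative-sampling behaviour analysable.
* **structures**: planted sites place the k liganding residues on a regular
  simplex of edge 6 Å (first-shell-like scale) with 0.4 Å coordinate
  jitter, Cβ 1.53 Å from Cα pointing at the site centroid; background
  structures use the same residue types at decoy geometry (edge 20 Å,
  jitter 1 Å). Both are embedded among 20 decoy residues in a 15–30 Å
  shell with 40 context atoms (C/N/O) within 5 Å of the site centroid, and
  a synthesized resolution in 1.2–1.9 Å. With zero jitter the planted
  inter-Cα distances equal the configured scale exactly, anchoring
  geometry tests.
* the **null variant** equalizes the positive and background distributions
  and zeroes the bias, giving datasets in which held-out MCC is centred on
  0 — the calibration check that the pipeline cannot manufacture signal.

What the fixtures deliberately do **not** emulate: real gap/geometry
statistics of zinc families, homology structure in the pool, coordination
distortions, crystallographic noise, or multi-site proteins. Passing the
planted-recovery tests therefore shows the pipeline recovers a learnable
signal it is pointed at and measures nothing when there is none; it does
not certify performance on real proteins, which depends on real training
catalogues (e.g. a curated zinc-site database) that users must supply.

## Problem sizes and defaults

Planted-recovery runs use 500-row balanced datasets (250 positives), 10
seeds per regime, with the pipeline's grid reduced to 4 points
(gini/entropy × depth ∞/8, 50 trees, sqrt) — the planted margin makes the
forest-size axis irrelevant, and the full 48-point grid's shape and
5-fold × 48 accounting are verified separately with small tree counts.
These sizes are the package's chosen experiment scale; all of them are
arguments, not constants.

## Known limitations

* Families outside the supported ten (rare compositions, sites completed
  by backbone carbonyls or waters) are out of scope by design.
* Sequence mode cannot represent sites split across chains (such sites are
  discarded from training data, matching the single-chain filter).
* The method locates liganding residue combinations, not the metal
  coordinate itself.
* The contrast parameterization (per-element ±1) is deliberately coarse;
  swap in a finer atom-typed table via `atom_table` if available.
* Probabilities are raw forest vote fractions; no isotonic/Platt
  calibration is applied.
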