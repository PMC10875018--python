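# Methods

`spatialtme` analyzes per-cell tables exported from multiplexed
immunofluorescence (mIF) imaging of tumor tissue — one row per segmented
cell with field coordinates, a tissue-compartment label and binary marker
calls — and quantifies the spatial contexture of tumor-infiltrating
T cells: who is there (phenotype gating), how many and where (compartment-
resolved densities and marker fractions), how close to whom (nearest-
neighbor distance statistics), how that relates to immune gene expression,
and whether it stratifies patient survival.  A seeded synthetic cohort
generator with planted ground truth provides the test bed.

## Phenotype gating

Gating maps the five marker booleans (CD3, CD8, FoxP3, Ki67, CK) plus the
granzyme-B (GrB) cytoplasmic mean intensity to ten overlapping phenotype
categories:

| category | definition | reading |
|---|---|---|
| T | CD3+ | all T cells |
| pT | CD3+ Ki67+ | proliferating T |
| Th | CD3+ CD8− FoxP3− | helper T (presumed CD4) |
| pTh | Th ∧ Ki67+ | proliferating helper |
| Treg | CD3+ FoxP3+ | regulatory T |
| pTreg | Treg ∧ Ki67+ | proliferating Treg |
| CD8T | CD3+ CD8+ | cytotoxic T |
| pCD8T | CD8T ∧ Ki67+ | proliferating cytotoxic |
| aCD8T | CD8T ∧ GrB+ | active cytotoxic |
| Tumor | CK+ (∧ CD3−) | tumor epithelial cells |

Categories are memberships, not a partition: pCD8T ⊂ CD8T ⊂ T, and a
CD3+CD8+FoxP3+ cell belongs to both Treg and CD8T — no exclusions beyond
the marker definitions are invented.  GrB positivity is intensity ≥ 0.25
on the [0, 1] scale; the boundary is included in the positive class (a
deterministic choice, configurable via `grb_cutoff`).  Rare CD3+CK+
co-positives (segmentation artifacts) are excluded from both the T-cell
lattice and the Tumor class by default; both exclusions are flags
(`t_excludes_ck`, `tumor_excludes_cd3`) and the excluded count is
queryable.  The subset lattice is enforced by construction and property-
tested over all marker combinations.

## Densities and fractions

Densities are reported per patient, category and compartment (tumor
epithelium and stroma; "other" tissue — necrosis, empty space — enters
neither numerator nor denominator) in cells/mm².  A patient's value pools
their fields: (Σ field counts) / (Σ field compartment areas).  The pooled
ratio is area-weighted and invariant to how cells happen to split across
fields, unlike the mean of per-field densities; the choice is pinned by a
test.  Marker-positive fractions (percent Ki67+ or GrB+ within a parent
category and compartment) use the same pooled counts.  Zero compartment
area or zero parent count yields a missing value with a reason code,
never a silent zero.

## Nearest-neighbor distances

For an ordered category pair (A, B), each A-cell contributes its Euclidean
distance (µm) to the nearest B-cell *within the same imaged field* —
fields are separate high-magnification images, so cross-field distances
are undefined.  A cell in both categories never matches itself (exclusion
by cell id); a field without B-cells contributes nothing.  Distances from
T-cell categories to tumor cells are restricted to source cells that are
not intraepithelial (compartment ≠ epithelium), since T cells already
inside the epithelium would trivially dominate the statistic; targets are
all tumor cells regardless of compartment.  The per-patient summary is
the median of per-cell distances pooled across fields (sample-size-
weighted, pinned by test), and the cohort-level "overall nearest radius"
is the median over patients of the per-patient median CD3+ → tumor
distance — the pinned interpretation of a cohort-wide T-cell-to-tumor
proximity scale.  Nearest-neighbor search uses a k-d tree and is tested
for exact agreement (≤ 1e-9 µm) with an O(n²) brute force.

Inter-metric correlation matrices (densities among themselves, distances
among themselves) use Spearman rank correlation by default with pairwise-
complete observations.

## Gene-expression association

Per-patient metrics are correlated (Pearson by default) with each gene of
three editable plain-text panels: the 20-gene Immunologic Constant of
Rejection signature (Th1 signaling: IFNG, TBX21, CD8A, CD8B, IL12B,
STAT1, IRF1; chemoattraction: CXCL9, CXCL10, CCL5; cytotoxicity: GNLY,
PRF1, GZMA, GZMB, GZMH; regulation: IDO1, CTLA4, CD274, PDCD1, FOXP3), a
chemokine-signaling panel and a cell-cell-interaction panel.  The two
KEGG-style panels are curated representative lists shipped as text files,
deliberately not live database exports (database versions drift; edit the
files or point the config at your own).  Loose aliases sometimes seen in
signature listings (PRF, CD8A/B) are normalized to HGNC symbols.

Distance metrics are negated before correlating, so r > 0 uniformly reads
"higher expression ↔ shorter distance", matching the direction of the
density convention; the flip is recorded per row and disabling it returns
exactly −r (tested as an involution).  Fewer than 3 complete pairs or a
zero-variance vector yields a missing value.  No multiple-testing
correction is applied to the correlation tables; a Benjamini–Hochberg
utility is provided but off by default.

## Survival analysis

Patients are dichotomized at the cohort median of a metric; strictly
above the median is "high" (ties go to "low" — the literal reading of
"above the median", pinned by test; note the worst-case group imbalance
under this rule is 2·ties−1, reached when the median falls inside a tied
block).  Groups are compared by Kaplan–Meier product-limit curves and the
log-rank (Mantel–Cox) test.  Prognostic modelling is univariate Cox
proportional hazards per covariate (Wald tests, Efron tie handling — the
least biased of the common tie approximations), then one multivariate
model over exactly the covariates with univariate p < 0.05 (strict
inequality; boundary excluded).  Hazard ratios carry 95% Wald intervals
exp(β ± 1.96·se).  Clinical covariates are encoded as: age continuous,
male vs female, right- vs left-sided, adjuvant yes/no, AJCC III/IV vs
I/II, MSI-H vs MSS, CMS2–4/Mixed vs CMS1, ICR Medium/High vs Low, metric
high vs low.  Estimation is delegated to lifelines and cross-checked in
tests against hand-computed product-limit and O−E tables.  Schoenfeld-
residual proportionality p-values are reported but never gate results;
exact collinearity and non-convergence are flagged, never silently
dropped.  OS and PFS are independent analyses; competing risks are out of
scope.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes — 90
patients × 4 fields of 670 × 500 µm (a typical 20× multispectral field)
by default — with planted, recoverable structure:

* **Geometry.** Tumor epithelium is a union of 5 random discs (radius
  90–200 µm) rejection-sampled until its area fraction is ≥ 0.30,
  mirroring the tumor-region field-selection rule; 2 small discs form
  "other" tissue; the remainder is stroma.  Areas come from exact polygon
  geometry (shapely) and the per-field summaries are consistent by
  construction.
* **Tumor cells.** Homogeneous Poisson on the epithelium mask at
  2000 cells/mm².
* **T cells.** Each base class (Th, Treg, CD8T) is a Thomas cluster
  process — cluster parents at 12/mm² with Gaussian offspring
  (σ = 30 µm) — sharing one parent set across classes so that densities
  co-vary within a field (coordinated infiltration), then thinned to
  compartment-specific planted intensities.  Defaults (cells/mm²,
  epithelium/stroma): Th 90/595, Treg 30/150, CD8T 35/160 — helper-T
  dominance, Treg ≈ CD8T, denser infiltration in stroma, with the
  epithelial Th level matching the scale reported for infiltrated colon
  tumors.  All T-cell intensities scale by exp(0.35 · latent) where
  latent ~ N(0, 1) is the patient's immune-activity factor.  A planted
  offset Δ (default 0) displaces Treg cluster centres from the shared
  parents, increasing Treg-to-effector distances monotonically in Δ.
* **Markers.** Ki67 probabilities (epithelium/stroma): Th 0.337/0.15,
  Treg 0.25/0.12, CD8T 0.148/0.08 — higher proliferation inside the
  epithelium.  GrB intensity is a two-component Beta mixture fully
  separated at 0.25 (actives: 30% of epithelial, 12% of stromal CD8 T
  cells), so the gate recovers the planted active fraction exactly.
* **Expression.** Each panel gene is a + r·z + √(1−r²)·ε with z the
  standardized latent, planting corr(latent, gene) exactly (r = 0.7 for
  the ICR panel, 0.5 for the other panels).  The ICR class label is the
  latent tertile, making class-wise density/distance contrasts
  meaningful.
* **Survival.** Exponential proportional hazards on realized spatial
  covariates: log-HR log(0.5) on above-median stromal Treg density (OS)
  and log(0.281) on above-median Treg → Th nearest distance (PFS) — both
  protective, the effect sizes taken from the magnitudes reported for
  these markers in colon cancer — plus log(2.0) on AJCC III/IV, with
  exponential censoring (0.12/yr, capped at 12 years).  Because the
  hazard acts on the metrics the pipeline itself measures, median-split
  Cox analysis recovers the planted hazard ratios up to sampling noise.

Identical (parameters, seed) reproduce the cohort byte for byte; all
generated tables pass the I/O validators.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: segmentation and phenotyping error (marker
calls are exact), spectral bleed-through, tissue architecture beyond
disc-union masks (no gland morphology, no invasive margin), spatial
interaction between T-cell subsets beyond shared cluster parents and the
planted offset, non-proportional hazards, and correlated censoring.
Passing recovery tests demonstrate that the estimators are correct under
the stated model, not that the model captures colon-cancer biology.

## Numerical and design choices

* Ties in nearest-neighbor search are broken by distance value only;
  identities are never reported.
* Medians use the mid-mean convention for even counts (numpy default).
* Undefined quantities (zero area, empty parent set, no targets, zero
  variance, < 3 pairs) are always missing-with-reason, never 0/∞.
* Float TSVs round-trip exactly (shortest-repr writing,
  `float_precision="round_trip"` reading); rerunning any stage on
  identical inputs reproduces identical bytes, verified by SHA-256
  manifests.
* Coordinates are µm with origin at the top-left of each field; an
  export in pixels can be accommodated by scaling before ingest.
* Problem sizes in the test-suite recovery checks (e.g. 500 calibration
  fields, 1000-replicate error-rate calibrations, n = 200 patients for
  correlation recovery, n = 500 for hazard-ratio recovery) were chosen as
  the smallest sizes at which the Monte-Carlo error is comfortably inside
  the assertion tolerances.

## Known limitations

* The overall-nearest-radius construction (median of per-patient median
  CD3+ → tumor distances) is one defensible reading of a cohort-level
  proximity radius; alternatives (pooling all cells, other source
  subsets) are not implemented.
* Whether density denominators should be compartment area or total
  tissue area is a field-level ambiguity; compartment area is used,
  matching the "in the epithelium / in the stroma" phrasing of
  compartment-resolved reporting.
* The Cox stage fits unpenalized models; with few events and many
  selected covariates the multivariate fit may be flagged as unstable
  rather than regularized.
* The two KEGG-style panels are representative curated lists, not
  versioned pathway exports.
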