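# Methods

This note documents the models, conventions and design choices behind
`mirsig`, in the order the pipeline runs them.

## Synthetic cohort model

The generator emulates a two-compartment (primary NSCLC vs brain
metastasis) nCounter-style miRNA profiling study so that every downstream
stage can be exercised against known truth.

**Panel.** 827 endogenous probes, 5 housekeeping probes, 6 positive and 6
negative controls. Ten endogenous probes carry the 11-miRNA differential
signature; the probe for miR-199a-3p/miR-199b-3p is shared because the two
mature sequences are identical, so a hybridization assay cannot distinguish
them — this is what makes "10 probes covering 11 miRNAs" reproducible. The
remaining 817 endogenous probes use synthetic placeholder names
(`mir-syn-0001` …) with baselines spread deterministically over
log2 ≈ 5–12 (≈ 32–4000 counts); the real panel's probe list is not public
and nothing downstream depends on the filler names.

**Cohort.** 25 patients; patients P01–P14 contribute a primary sample;
P01–P05 contribute two metastatic samples and everyone else one, giving
14 + 30 = 44 samples. Only the totals are constrained by the emulated
design; the per-patient metastatic allocation is this package's fixed,
documented table.

**Signature.** Five miRNAs up in metastasis (miR-9-5p, miR-129-2-3p,
miR-124-3p, miR-219a-5p, miR-219a-2-3p) and six down (miR-199a-5p,
miR-199a-3p, miR-199b-3p, miR-199b-5p, miR-150-5p, miR-142-3p). Default
magnitudes are +3.0 and −2.0 log2 units — generator choices large enough
that recovery failures indicate pipeline defects rather than power limits,
while leaving the null probes dominant in the multiple-testing family. The
five up-miRNAs are planted near background in primary tissue
(baseline ≈ log2 20) and the six down-miRNAs abundant
(baseline ≈ log2 2000), reproducing the absolute-expression contrast of
the emulated study.

**Count model.** For endogenous and housekeeping probes

```
count[p, s] ~ NegBin(mean = L_s · 2^(b_p + u_pat(s) + δ_ps), size = r)
              + Poisson(λ)
```

with `r = nb_dispersion = 10` (CV² ≈ 0.1 of extra-Poisson noise, typical
of FFPE nCounter data), `λ = background_mean = 12` (also the
negative-control mean), `u_pat ~ N(0, 0.25)` per patient on the log2 scale
(shared biology between a patient's samples), and
`L_s ~ LogNormal(0, 0.3)` per sample applied to every probe including
housekeeping — this is what makes housekeeping normalization non-trivial
and recoverable. `δ_ps` is the signed planted log2 fold change in
metastatic samples for probes annotated to a planted miRNA. Positive
controls are NB draws around the panel's fixed geometric ladder of means
(2^14 down by factor 4), scaled by `L_s` like all probes; negative
controls are pure Poisson(λ). Moment identities used by the tests:
`E = m + λ`, `Var = m + m²/r + λ`.

**What the generator does not emulate:** raw RCC files, imaging QC,
positive-control linearity QC, FFPE degradation gradients, batch/lane
effects, or correlations between miRNAs beyond the shared patient effect.
Passing tests therefore demonstrate correctness of the computations and
calibration under this model, not performance on real FFPE data.

## Normalization

Per-sample scale factor `sf_s = mean_s(geomean_HK) / geomean_HK(s)` — the
cohort arithmetic mean of housekeeping geometric means as reference, the
convention of nSolver-style processing. Which five housekeeping genes the
assay uses is treated as a probe-class annotation, not a gene list. A zero
housekeeping count raises an error rather than being pseudo-counted: a
silent offset would distort every value in that sample. Normalization is
idempotent (re-normalizing yields factors 1 within 1e-9) and equivariant
under sample permutation.

The background threshold (mean + 2·SD of negative controls per sample,
sample SD) is annotation for reports only; no probe is filtered by it.

## Differential expression

Welch's unequal-variance t-test per endogenous probe on `log2(x̃ + 1)`,
metastasis vs primary, two-sided. Choices that matter:

- **Welch, not pooled-variance:** group sizes are unequal (14 vs 30) and
  the planted effects change variance on the count scale.
- **Pairing ignored:** the cohort is only partially matched (14 of 44
  samples have a within-patient counterpart), so the global contrast
  treats groups as independent.
- **Offset +1** avoids log(0) on background-level counts.
- **Degenerate variance:** if both group variances are zero the test is
  resolved by convention — p = 1 for equal means, p = 0 otherwise.
- **BH family = endogenous probes only;** controls are never tested.
- **log2fc attenuation:** the reported `log2fc` is the group difference of
  mean `log2(x̃+1)`. For probes near background this estimate is
  deliberately naive: additive background λ compresses it, e.g. a planted
  +3.0 on a baseline-20 probe appears as ≈ log2((160+13)/(20+13)) ≈ 2.4.
  No background subtraction is applied, matching the normalized-counts
  convention of the emulated workflow; the attenuation is a property of
  the estimator, with direction and significance unaffected.

`bh_adjust` is the Benjamini–Hochberg step-up
(`q_(i) = min_{j≥i} m·p_(j)/j`, capped at 1); the test suite checks it
exactly against a literal brute-force implementation. Under the default
planted signature BH controls the false-discovery *rate*, not the
probability of any false call: with ≈ 10 near-certain discoveries among
827 probes the step-up threshold is ≈ 11·0.05/827 ≈ 6.6e-4 and the chance
of at least one false positive per dataset is ≈ 0.4. Recovery is therefore
assessed as "all planted probes called with correct directions", and false
positives are controlled by the separate null-cohort calibration (empty
signature), where the any-call probability equals α ≈ 0.05.

Signature expansion is mechanical bookkeeping: each significant probe
yields one row per annotated miRNA, so the shared miR-199-3p probe
produces two rows with identical statistics.

## Diagnostics

- **Clustering:** samples clustered on Euclidean distance with complete
  linkage. Input is `log2(x̃+1)` with rows standardized to zero mean/unit
  variance (the heatmap convention; zero-variance rows are dropped as they
  carry no contrast). "Two major clusters" is operationalized as the k = 2
  cut, obtained by undoing the last merge. The clustering-contrast
  property (significant-probe clustering yields a purer metastasis
  cluster than all-probe clustering) mirrors the supervised/unsupervised
  contrast expected in such cohorts.
- **Paired scatter:** per patient with both compartments, R² is the
  squared Pearson correlation of `log10(x̃+1)` across endogenous probes —
  identical to least-squares regression R². Zero-variance vectors raise an
  error (tolerance 1e-12 relative, absorbing scale-factor float noise).
- **ROC/AUC:** midrank Mann–Whitney formula, `AUC = U/(n1·n2)` with
  half-credit ties; per probe, oriented to ≥ 0.5 with the orientation
  (metastasis_high/metastasis_low) recorded — it coincides with the sign
  of the probe's log2fc. The suite verifies exact agreement with
  exhaustive pair counting and with scikit-learn's `roc_auc_score` as an
  independent cross-check.

## Target-gene scoring

TargetScan-style context scores are ≤ 0, more negative = stronger
predicted repression. Per gene the pipeline tracks site-level **events**
and distinct-miRNA **links** separately for the up- and down-miRNA groups,
sums `|context score|` per group, drops genes whose cumulative score
(`s_up + s_down`) falls below a threshold (default 0.01 — read as a
magnitude threshold since the scores themselves are non-positive), and
computes

```
pseudo_logfc = w_down · s_down − w_up · s_up
```

Positive values predict upregulation in metastasis (targets of
down-miRNAs), negative the reverse. Two weighting modes are provided
because the source workflow's exact formula is ambiguous between "events
and links per gene" and "total interactions per group": `simple`
(w = 1, the default) and `group_scaled`
(`w_D = N_D / (N_up + N_down)` with `N_D` the group's total retained event
count). Both satisfy the direction law (single-group genes never cross
zero) and, in simple mode, the mixed-attenuation law
(`|s_d − s_u| ≤ max(s_d, s_u)`): a gene targeted by both directions never
outranks the same total score concentrated in one direction. Ranking is by
`|pseudo_logfc|` descending with ties broken by cumulative score, then
gene symbol. Multi-transcript genes collapse to the gene symbol by
summation; genes absent from the interaction table are absent from the
output.

## Hub networks

Edges are directed on disk (`source TAB mode TAB target`,
mode ∈ {A, I, activation, inhibition}; self-loops rejected, exact
duplicates collapsed) but treated as undirected for connectivity. Given a
direction group's target genes, the induced subgraph is built and genes
with zero induced connections are removed in a single pass — connectivity
is mutual, so no iterative pruning can follow. `connection_count` is the
number of distinct surviving neighbors (configurable to raw edge counts,
since it is unknowable whether a published count treats parallel A and I
edges as one or two connections). Every node is annotated with the group's
predicted gene direction: hubs of up-miRNA targets are `down_in_bm`, hubs
of down-miRNA targets `up_in_bm`. No interactome ships with the package —
the reference analyses used a proprietary edge base — so hub results are
always relative to a user-supplied (or generated) edge table.

## Pipeline and reproducibility

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seed + config produce bit-identical
count files and reports (config hash and seed are embedded in the report
provenance). The problem sizes used by the test suite and the acceptance
script — 20 signature cohorts and 20 null cohorts at the full 827-probe,
44-sample design, 1000-case oracle sweeps for BH/accumulation/hub
equivalence, ≤ 8-sample brute-force agglomeration — were chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo
tolerances meaningful.

## Known limitations

- The count model is parametric and stylized; it does not claim to match
  real FFPE nCounter moments beyond over-dispersion and library-size
  variation.
- Fold-change estimates of near-background probes are attenuated (see
  above); the package reports the naive estimator by design.
- The paired structure of the cohort is used only for scatter
  diagnostics, not for the DE model (no mixed effects, no
  empirical-Bayes moderation).
- Pathway enrichment/perturbation analysis and literature-verified
  interaction lookup are out of scope; the hub stage consumes whatever
  edge table it is given and inherits its completeness and biases.
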