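# Methods

## Scope and model

`periobiome` implements the statistics of a multi-arm oral-microbiome
intervention study.  The observational unit is one oral sample per
animal; the data are (a) a taxa × samples read-count table annotated
with taxonomic level (genus/species) and kingdom (bacteria/virus),
(b) sample metadata (group, animal, total reads), (c) a per-animal
immune-marker panel (IL-1β, IL-6, TNF-α, IFN-γ, CCL2, CXCL2, TGF-β1),
and (d) bench-assay tables (qPCR copy numbers, CT values, 28-site
bone-loss vectors, per-surface defect flags, IgG ODs).  The pipeline
starts from the annotated count table; sequencing, assembly and
taxonomy assignment are upstream and out of scope.

## Normalization and filtering

Counts are rescaled per sample to one million reads (RPM).  RPM is
computed once: subsequent taxon filtering does not renormalize, so each
sample keeps its original per-million basis and values stay comparable
across filter settings.  The default processing order is
normalize → exclude low-coverage samples → filter taxa with mean
RPM < 1 across the retained samples.  Order matters (a dying sample
drags taxon means); it is fixed, configurable, and recorded in the
table's provenance list, as are all removed taxa/samples.  Exclusion
supports both an explicit id list (studies typically name their dropped
samples) and a minimum-raw-reads threshold.  The mean-RPM cuts are
strict: a taxon at exactly the threshold is retained by the 1-RPM
filter and removed by the 500-RPM ordination cap.

## Diversity, content, ordination

Shannon diversity `H = −Σ pᵢ ln pᵢ` is computed in nats per sample over
the positive entries of one kingdom of the filtered species table (log
base and level are options).  Group content is the per-sample total RPM
of a kingdom, summarized as mean ± t₍n−1,0.975₎·s/√n.  All two-group
comparisons use the pooled-variance two-sided t-test; a zero pooled
variance is flagged degenerate with p = 1 (equal means) or p = 0 —
degenerate cases are reported, never silently dropped.

Ordination removes species whose *mean* RPM across retained samples is
≥ 500 so that ubiquitous dominant species do not determine the
geometry (the mean-across-samples reading makes the species-level
decision well defined).  Bray–Curtis dissimilarities feed classical
scaling: Gower-center `B = −½ J (D∘D) J`, eigendecompose, coordinates =
eigenvector · √λ for λ > 0.  Bray–Curtis is non-Euclidean, so negative
eigenvalues occur; they are reported but excluded from
explained-variance fractions, and no Lingoes/Cailliez correction is
applied by default.  Axis signs are fixed by making each axis's
largest-|coordinate| entry positive, for reproducible plots.  Group
ellipses assume a bivariate normal with the sample mean and covariance;
semi-axes are `√(λᵢ · χ²₂,level)` (χ²₂,₀.₉₅ = 5.9915) along the
covariance eigenvectors — the known-covariance coverage contour rather
than the F-based prediction ellipse (switchable by supplying a
different level/quantile).  Singular covariances (collinear points) are
flagged degenerate.

## Differential abundance and immune correlation

Abundances are transformed to `y = log₁₀(RPM + 0.1)`; the pseudocount
is 0.1 RPM, so the floor is exactly −1.  For each non-reference group
and taxon, Δ = mean(y_group) − mean(y_ref) with a pooled t-test;
fold change is defined as `10^Δ`, the ratio of geometric means of
(RPM + 0.1).  Benjamini–Hochberg runs within each (comparison,
taxonomic level) family across its taxa — whether genus and species
should share one family is not settled practice, so the family is
per-level and configurable.  Tiers are `***` q < 0.1, `**` q < 0.2,
`*` q < 0.3.  Tests are two-sided (effects run in both directions).

Taxa with any non-empty tier in any comparison are correlated with each
immune marker across all retained animals, pooling all groups; marker
values receive the same `log₁₀(x + 0.1)` transform as abundances.
Pearson r gets a t-based p (df = n − 2); BH runs per marker across
taxa.  Pairing is by animal with pairwise deletion of missing marker
values (n is reported); constant vectors are flagged undefined and
excluded from the BH family.

## Host assays

Pathogen load is 100 × pathogen copies / total-16S copies.  Detection
frequency reports the exact percent plus a nearest-integer display
value (ties away from zero).  Relative expression uses the comparative
CT method with the reference statistic being the arithmetic mean of
reference-group ΔCT (the conventional form): ΔCT = CT_target −
CT_GAPDH, ΔΔCT = ΔCT − mean ΔCT_ref, fold = 2^−ΔΔCT; the
reference-group geometric mean fold is 1 by construction.  Bone loss is
the arithmetic mean of exactly 28 site measurements per mouse (7 molar
sites × 2 sides × 2 jaws); any other count is an error.  Intrabony
defects are compared between groups by Pearson χ² on the 2×2 table of
defect/no-defect out of 72 surfaces per group, without Yates continuity
correction by default (available via flag).  Multi-group readouts use
one-way ANOVA with Tukey HSD via the studentized range.

## Synthetic studies

The generator emulates the sequenced arm of the study design: 8 groups
(control, infection, three treatment-only arms, infection + each
treatment) × 6 animals, 80 bacterial + 40 viral species by default.
Per taxon, log₁₀ relative abundance is Gaussian: a baseline (bacteria
N(0, 0.7); viruses shifted −0.8, i.e. ~a decade rarer) plus the group's
effect shift, with dispersion σ = 0.3 log₁₀ units by default.  The
composition is the softmax of these log abundances; reads are
multinomial given a Poisson library size (default mean 10⁵ — RPM is
depth-invariant, so depth is a free desk-scale parameter; the
calibration studies at 2000 taxa use 2×10⁶ so the average taxon keeps
~10³ reads).

Effects are multiplicative: an affected taxon's abundance is multiplied
by `fold^(1−ρ)` where ρ ∈ [0, 1] is the group's recovery (ρ = 0 full
infection effect, ρ = 1 control state).  The default effect structure
has two layers: focal taxa — three disease viruses (folds 4, 3, 2) and
one health-associated bacterium (fold 0.25), pinned at ~1% baseline
abundance so their differential abundance stands clear of counting
noise — and a 16-species moderate-abundance dysbiosis signature (8 up
×3, 8 down ×3) whose baselines sit below the 500-RPM ordination cap, so
infection visibly moves the Bray–Curtis geometry and treatment recovery
moves it back.  Without the second layer the focal taxa would all be
removed by the cap and the generated study could not show the
ordination recovery it is meant to emulate.  Default recovery: infection
ρ = 0, infection + nisin and infection + nisin-producing *L. lactis*
ρ = 0.9, infection + non-nisin *L. lactis* ρ = 0.5, non-infected arms
at the control state.  IL-6 is coupled to the strongest disease virus:
`log₁₀(IL6 + 0.1) = 0.5 + 1.0 · log₁₀(RPM + 0.1) + N(0, 0.3)`; other
markers are uncoupled log-normal noise.

The ground-truth object records, per (taxon, group), the exact expected
log₁₀ RPM under the model — the compositional normalizing constant's
expectation is evaluated by seeded Monte Carlo (2000 draws), so truth is
deterministic — plus the effect multipliers and coupling parameters.
All outputs are a pure function of (design, effects, seed).

What the generator does *not* emulate: read sequences and annotation
error, within-mouse longitudinal dynamics, taxon–taxon interaction
structure beyond compositional closure, and realistic zero inflation.
Passing tests therefore demonstrate correctness and calibration of the
statistics under a clean log-normal/multinomial world, not robustness
to annotation artifacts in real tables.

## Numerical choices

* Serialized abundance values carry 6 significant digits; counts are
  exact integers.  Parsing is locale-independent (dot decimal).
* PCoA treats eigenvalues below `max(λ₁, 1)·10⁻¹⁰` as zero (neither
  axes nor deficits).
* BH q-values are computed by the standard step-up (via statsmodels)
  and tested against a brute-force enumeration to 10⁻¹².
* Degenerate cases (zero variance, singular covariance, constant
  correlation vectors, zero χ² margins) are flagged or raised
  explicitly, never silently imputed.

## Calibration properties and their sharpness

On null studies (no planted effects; 2000 species, 6 vs 6 samples,
depth 2×10⁶) the per-taxon t-tests reject at 0.049 ± 0.005 at α = 0.05
across seeds.  For the BH step under a true null, the probability of
making *any* rejection at q < 0.1 equals 0.1 exactly (a property of the
procedure, not of this implementation); over 60 seeds we measure an
any-rejection rate of 0.100.  Consequently "zero rejections" holds in
90% of studies in expectation — a check demanding it in ≥ 18 of 20
fixed seeds sits exactly at that binomial mean and will fail for about
a third of seed windows even for a perfectly calibrated method; the
packaged test suite pins one such window and documents the observed
count.  Similarly, recovery of a 4-fold planted virus at FDR < 0.1
(σ = 0.15 log₁₀, 6 vs 6, BH over 120 species) has per-study power 0.85
measured over 60 seeds: the idealized noncentral-t power (δ =
log₁₀4 / (σ√(2/6)), giving 0.95) ignores compositional closure and the
shared per-sample normalization term, which any closed compositional
generator necessarily adds to the nominal dispersion.  The IL-6
coupling recovery (coupled taxon attains the most-positive correlation)
and the ordination recovery (treated centroids nearer control than the
infection centroid, first 4 axes) hold in 20/20 and 10/10 checked seeds
respectively.

## Known limitations

* Equal-variance t-tests on log-transformed compositions are the
  study-standard analysis, not a compositional method (no CLR/ALDEx2,
  no zero-inflation model, no covariate adjustment).
* Bray–Curtis PCoA coordinates depend on the abundance cap; the
  explained-variance fractions of any real dataset depend on that
  dataset and are not targets of the synthetic studies.
* The ΔΔCT fold changes propagate no amplification-efficiency error;
  copy numbers are consumed as given, whatever their standard-curve
  origin.
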