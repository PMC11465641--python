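# Methods

## Problem and data model

The package synthesizes concentrations of organic pollutants measured in
paired samples of oviparous reptile mothers and their offspring.  The unit of
observation (a *data point*) is one compound × one individual (or pooled
group) × one tissue.  Each observation carries its published value, unit,
measurement basis (wet, dry or lipid weight), a three-state censoring status,
and study metadata.  Individual values are preferred over group summaries;
where a study reports only group data, the geometric mean is used (the
arithmetic mean when a geometric mean is unavailable or undefined, e.g. with
zero members), and the number of pooled individuals is recorded.

Censoring is handled by accounting, never by imputation:

- **uncensored** — an exact value;
- **quantitatively censored** — below a *known* LOD/LOQ (treated as one
  threshold), so the value lies in [0, LOD] and still carries quantitative
  information;
- **qualitatively censored** — below an unreported limit; such observations
  carry no quantitative information and are excluded from all data-amount
  counts and from every ratio and correlation, but retained in the database
  and in the censoring audit.

## Harmonization

All concentrations and LODs are mapped by the identical composed transform:

1. unit → ng/g, with exact rational factors over the supported mass-ratio
   dialect (ng/g, µg/g, µg/kg, mg/kg, ng/kg, pg/g; ppm ≡ µg/g, ppb ≡ ng/g,
   ppt ≡ pg/g).  Factors are applied through `fractions.Fraction`, so the
   only rounding is the final binary float;
2. dry → wet weight where needed: `C_ww = C_dw × (1 − f_water)`, with the
   tissue water fraction from an explicit lookup table;
3. lipid normalization: `C_lw = C_ww / f_lipid`.

The lipid fraction is resolved through a strictly ordered fallback chain —
study-reported value, then a literature value for the same species and
tissue, then a literature value for an explicitly declared closely related
species (the relatedness map is an editable file; the shipped default groups
congeners/confamilials, e.g. marine turtles together).  The chosen source is
recorded on every record, as is the full conversion trace.  The lipid
fraction is interpreted on the same basis as the concentration at the moment
of normalization, which is why dry→wet conversion precedes it.  Records with
no lipid fraction at any level stay on the wet-weight basis with a
diagnostic.  Invariant checks use 1e-9 relative tolerance; all transforms
are exact scalings, so observed error is at the float-rounding level
(~1e-16).

## Molecular descriptors

Descriptors are consumed from local snapshot tables (no network access).
log K_ow provenance: experimental value > model estimate > explicit override
(used for compound families the estimation model lacks, such as chlorinated
paraffins, and for measured coelution peaks); the provenance label is stored.
A coelution receives a descriptor only if every member has it and the values
agree (integers exactly; reals within 1e-6 absolute — the agreement rule has
no published tolerance, and 1e-6 separates genuine table duplicates from
distinct congeners).  Compound sums never receive descriptors: a sum has no
single molecular structure.  Chemical-space summaries (per-class mean/range
per descriptor, zero-value fractions for charge, H-bond counts and TPSA) are
computed over unique compounds, with unassigned values excluded from means;
zero-value fractions are likewise over compounds with the descriptor
assigned, the only well-defined denominator.

## Transfer statistics

Pairs are formed per (study, mother, compound, maternal tissue, offspring
matrix) via an explicit mother-id linkage.  Two pairing policies: `per_egg`
(each egg its own pair) and `clutch_mean` (replicate eggs first collapsed to
the geometric mean of their uncensored values); which a real analysis should
use depends on whether egg replicates are treated as independent, so it is a
configuration switch, defaulting to `per_egg`.

The partition ratio is `R = log10(C_offspring / C_mother)` on a declared
common basis — lipid-normalized by default, wet weight for the PFAS view —
computed only when both sides are uncensored and positive; every ineligible
pair is reported with a reason.  R = 0 is the lipid-normalized equilibrium
expectation; the 10-fold band is closed (|R| ≤ 1), the conservative reading
of "within a 10-fold deviation".  Group summaries use type-7 (linear
interpolation) quartiles with 1.5×IQR whiskers clamped to the observed
extremes.  Maternal-tissue correlations are Pearson correlations of log10
lipid-normalized concentrations over co-measured (study, mother, compound)
observations, with Spearman emitted alongside since the appropriate
coefficient for such data is arguable; tissue pairs with fewer than
`min_pairs` (default 10) co-measurements are omitted.  Ratio-vs-lipophilicity
trends are least-squares fits of R on log10 K_ow per species × maternal
tissue × class (slope, intercept, slope SE, Spearman rank correlation), with
groups of n < 5 flagged and zero-variance-K_ow groups reported as having no
defined slope.

## Synthetic data generator

The generator's role is to produce datasets whose truth is known exactly, in
the same shapes the ingestion layer must face.  Per mother and compound a
latent lipid-normalized level `log10 C ~ Normal(mu_m, sigma_m)` is drawn,
shared across her tissues up to `Normal(0, sigma_tissue)` scatter; each egg
adds `alpha + beta·log10 Kow + Normal(0, sigma_e)`.  Records are then
*encoded* into each study's declared unit and basis (using the tissue's true
lipid fraction and, for dry-basis studies, the true water fraction), so
harmonization must invert the encoding — the round trip is exact to < 1e-9.
Censoring places each compound's LOD at quantile `q_lod` of the mother
concentration distribution; records below it are censored, a share `p_qual`
of them qualitatively.  Clutches are reported as geometric means with a
per-study pooling probability.

Default fixture (chosen once to mirror the heterogeneity of real multi-study
databases): six studies — two data-rich "flagship" studies (*Malaclemys
terrapin* with four maternal tissues, *Enhydris chinensis* with six), one
dry-weight-basis *Chelonia mydas* study (water fraction 0.667), and three
small whole-egg/yolk-only studies — a 20-compound panel spanning
log K_ow ≈ 4.5–7.6 across PCB/OCP/HFR/PFAS/PAH/phthalate classes with
realistic literature K_ow values; `mu_m = 2` (100 ng/g lipid), `sigma_m =
0.8` (typical order-of-magnitude spread of field burdens), `alpha = −0.2`,
`beta = 0`, `sigma_e = 0.25`, `sigma_tissue = 0.05`, `q_lod = 0.73`,
`p_qual = 0.5` (roughly three-quarters of records censored, half of those
qualitatively — the regime that makes censoring-aware accounting worth
testing).  What the generator does **not** emulate: toxicokinetics over
time, class-specific transfer mechanisms (PFAS protein affinity, PAH
metabolization), inter-species differences in alpha, or correlated compound
mixtures.  Passing recovery tests therefore demonstrates that the pipeline's
bookkeeping and statistics are correct, not that real transfer follows this
model.

Analytic expectations accompany the generator: expected median ratio
`alpha + beta·mean(log Kow)`, and the expected censored fraction as the
record-count-weighted normal CDF below the LOD, accounting for the different
marginal variances of mother-tissue, per-egg and pooled records.

## Validation conditions

Pre-registered configurations (in `mtdb.validation`) drive both the test
suite and `scripts/acceptance.py`:

- **offset/slope recovery** — one study, 200 mothers × 2 eggs, liver vs
  whole egg, `sigma_e = 0.2`, censoring off, all other noise off, so per-egg
  ratios are i.i.d. `alpha + beta·log Kow + eps` and standard errors apply;
  run once with `alpha = −0.5, beta = 0` (median check) and once with
  `beta = −0.2` (slope check).
- **censoring recovery** — 150 mothers × 20 compounds, one tissue, one egg,
  all noise off, `q_lod = 0.73`, `p_qual = 0.5`: every mother × compound
  cluster is fully concordant, so the censored fraction is binomial over the
  3000 independent clusters and 99% bounds are exact.
- **banding** — noiseless transfer with `alpha = −0.3`, `beta = 0.05`, so
  every compound's true offset lies well inside (−1, 1) and all ratios must
  classify within the 10-fold band.

These sizes keep the full suite and the acceptance script within seconds on
one CPU while leaving comfortable statistical margins.

## Known limitations

- Censored observations are excluded from ratios rather than modelled;
  medians of ratios are therefore biased upward wherever censoring truncates
  the low tail (visible in the worked example: median R −0.10 against a true
  offset of −0.2).  Survival-analysis estimators for nondetects are out of
  scope by design.
- The duplicate-sum exclusion is scoped per study and keyed on canonical
  compound ids; sums whose membership a study does not enumerate cannot be
  checked and are kept.
- The species-relatedness fallback for lipid fractions is a flat editable
  list, not a phylogeny; no distance weighting is attempted.
- No mixed-effects or phylogenetic modelling of ratios; group summaries and
  per-group regressions only.
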