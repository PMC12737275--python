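# Methods

This note documents the models, parameter choices and numerical
conventions behind `pahrisk`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Risk equations and units

Carcinogenic risk is computed on benzo[a]pyrene equivalents,
BaPeq_i = C_i·TEF_i, with a single slope factor applied to every
congener's BaPeq dose:

    ILCR_i = BaPeq_i · CSF · IR · EF · ED / (BW · AT),  TILCR = Σ ILCR_i
    HQ_i   = C_i · IR / (RfD_i · BW),                   HI    = Σ HQ_i

Concentrations enter the API in µg/kg wet weight and intake rates in
g·person⁻¹·day⁻¹; the equations work in mg/kg and kg/day. Both ×10⁻³
conversions are defined once, in `data_io`, and used nowhere else, so a
double conversion cannot occur.

Default adult parameters: BW 60 kg, IR 49.3 g/day, EF 365 day/yr,
CSF 7.3 (mg·kg⁻¹·day⁻¹)⁻¹. The carcinogenic pathway averages over a
70-year lifetime (AT = 365 × 70 days) with ED defaulting to 70 years, so
ED/AT reduces to 1/365; ED = 30 is exposed as an option, in which case
ILCR scales linearly (the implementation keeps AT fixed at 365 × 70 for
this pathway). The non-carcinogenic pathway uses AT = 365 × ED. Risk
categories follow the usual bounds: ILCR below 10⁻⁶ negligible, between
10⁻⁶ and 10⁻⁴ inclusive cautionary, above 10⁻⁴ unacceptable; both
boundary values classify as cautionary.

Registry constants are keyed by full compound name; some published
tabulations scramble the three-letter labels of acenaphthene /
acenaphthylene / fluorene, so `pahrisk` pins the conventional mapping
(Nap, Acy, Ace, Flu) and the ring assignments 2:2, 3:4, 4:4, 5:4, 6:2.
The BghiP TEF is kept at 0.1 as tabulated in the source constants (some
TEF schemes use 0.01); no alternative TEF schemes are provided.

## Monte Carlo layer

Stochastic inputs and defaults:

| variable | default distribution | rationale |
|---|---|---|
| BW | normal(60, 6) kg, truncated > 0 | 10% CV around the adult default |
| IR | log-normal, mean 49.3 g/day, CV 0.3 | intake rates are right-skewed |
| ED | uniform(30, 70) yr | the two tabulated bounds, no interior information |
| EF | point 365 day/yr | daily consumption assumption |
| BaPeq | log-normal fitted to sample totals | see below |

The concentration input follows the log-normal convention: sample-level
BaPeq totals are log-transformed, screened with the Shapiro–Wilk test and
fitted by maximum likelihood (log-scale SD uses the sample, ddof = 1,
convention). Drawing the BaPeq *total* — rather than 16 congeners
independently — matches how the deterministic equations consume the data
(TILCR is linear in BaPeq) and avoids inventing a 16-dimensional
dependence structure. For HI, the drawn total concentration is
apportioned over congeners with a fixed composition vector (the mean
congener fractions), again exploiting linearity. All distribution choices
are overridable per variable; none of the fitted-parameter defaults
should be read as measured population values.

One seeded generator per run with a fixed draw order (bw, ir, ed, ef,
bapeq, concentration) makes runs bit-reproducible. The convergence check
sweeps iteration counts (default 4000/7000/10000/13000) on a *common
growing draw stream*, so consecutive counts share their leading draws and
the tabulated change in the 95th percentile reflects added iterations
rather than independent resampling noise; stability is declared when the
final relative change is below 1%. With point-mass inputs the simulation
reproduces the deterministic TILCR exactly (same floating-point
expression order).

## PMF solver

The receptor model minimizes Q = Σ((x − ĝf)/u)² over nonnegative G
(n × k contributions) and F (k × p profiles). The solver uses
multiplicative (Lee–Seung-style) updates under 1/u² weights; each
iteration provably never increases Q, which is asserted at runtime.
Defaults: 20 random starts (uniform(0.1, 1) scaled to the data
magnitude), max 2000 iterations, relative-decrease tolerance 10⁻⁸,
denominator guard 10⁻¹². The best start by Q is reported in the
canonical scaling (profile rows summing to 1, factors ordered by mean
contribution). No rotational (FPEAK-style) exploration is performed.

Diagnostics: per-congener r² between observed and reconstructed
concentrations, standardized residuals (x − ĝf)/u, and
Q_expected = n·p − k(n + p), the conventional degrees-of-freedom count.
The factor-count scan reports Q and Q/Q_expected for each k; on mixtures
with a true source count the drop in Q flattens sharply past it.

Factor labeling assigns each factor the source whose disjoint marker set
(coal combustion: BaA/Chr/BbF/BkF/BaP; petroleum: Nap/Ace/Flu/Acy/Phe/Ant;
biomass burning: Fla/Pyr; traffic: DahA/InP/BghiP) carries the largest
summed column-percentage mass; ties break toward the first-listed source
and duplicate labels are reported with a warning.

Solution uniqueness: an exact nonnegative factorization is generally
unique only up to permutation and scale when profiles are well separated
and some samples are (near-)pure in each source; the ground-truth
decomposition tests therefore use disjoint-support profiles with pure
samples. On overlapping profiles, recovered factors are validated by
cosine similarity after optimal matching (exhaustive assignment, k ≤ 4).

## Source-oriented risk attribution

Because the risk equations are linear in concentrations, the per-factor
parts g_ih·f_hj decompose HI and TILCR additively. Shares are computed on
the model reconstruction ĝf, not on the observed matrix — that choice
makes the 100% closure exact; residual observed-minus-reconstructed mass
is available from the model separately. Samples are pooled by summing
risks (default); a per-sample-share-then-average mode is provided. Ring
class shares use the same weights grouped by ring count. Note the shares
are independent of the exposure parameters, which enter all congeners as
a common factor.

## Synthetic data generator

The generator emulates the data-generating process the analysis assumes,
at the study's conditions:

- **Four-source mixtures** X = G·F ∘ (1 + ε). Profiles encode the marker
  structure of the four sources; numerically they are derived from
  per-congener column shares (the fraction of each congener's mean burden
  attributed to each source), with tracer entries following reported
  factor loadings (e.g. Nap dominated by petroleum, BghiP by traffic) and
  the remaining mass split as a synthetic convention. Mean source
  contributions are fixed so that the expected congener composition
  equals the bundled survey means exactly.
- **Contributions** are independent per-source log-normals, sdlog 1.3 by
  default — chosen so the generated per-congener coefficients of
  variation (≈1.2–1.7) match the dispersion of the survey marginals
  (median CV ≈ 1.2).
- **Noise** is multiplicative truncated-normal with relative SD
  `noise_cv` (default 0.1), clipped at zero, reflecting the relative-error
  character of chromatographic quantification.
- **Uncertainties** for the PMF objective follow the receptor-model
  convention u = 0.10·x + (5/6)·LOQ, with instrument LOQs converted to
  tissue units by the fixed extract-volume/sample-mass factor 0.2
  (L per kg); the uncertainty inputs are a documented assumption, not
  measured values.
- **Survey-like matrices** draw each congener from an independent
  log-normal moment-matched to the survey mean/SD. Species multipliers
  (crayfish 1.3, yellow catfish 1.15, crucian carp 0.9, common carp 0.8 —
  synthetic conventions) are renormalized per congener so grand means are
  preserved while the species total-burden ordering holds; yellow catfish
  gets an extra 1.4× enrichment on 5–6-ring congeners, reproducing its
  high carcinogen fraction.

What passing tests on these data do **not** show about real data: the
survey-like generator has independent congener marginals (no
congener–congener correlation beyond the mixture structure), so its total
burden is less dispersed than really observed; there is no spatial or
seasonal structure; and the PMF validation demonstrates recovery of the
generator's source structure, not of any real lake's sources.

## Numerical and testing conventions

- Fit-diagnostic regime: with multiplicative noise of relative SD ν, the
  large-sample per-congener r² is bounded above by 1 − ν²(1 + 1/CV²),
  which equals 0.99 exactly at ν = 0.1 in the high-CV limit. The
  diagnostics fixture therefore runs at noise_cv = 0.05, where the fitted
  models reach r² ≥ 0.99 for all congeners with ≥ 99% of standardized
  residuals within ±3; profile-recovery checks run at noise_cv = 0.1.
- Monte Carlo sanity checks use closed-form log-normal tails and product
  means as oracles; PMF correctness on tiny instances is checked against
  a brute-force grid over simplex profiles with exact weighted-NNLS
  contributions.
- Sample sizes in tests (n = 200 mixtures for recovery, n = 5000 for
  moment-matching, 10⁴–10⁵ Monte Carlo draws) are the package's chosen
  sizes at which the asymptotic checks are statistically comfortable.
- Degenerate inputs are rejected loudly: negative concentrations,
  non-positive uncertainties, constant samples for Shapiro–Wilk,
  factor counts violating k(n + p) < n·p, zero total risk in shares.

## Known limitations

- One adult exposure scenario; no age stratification, no dermal or
  inhalation routes.
- The TILCR applies one CSF to all congeners' BaPeq, the standard
  BaP-equivalents simplification.
- PMF reports the base solution only (no bootstrap/displacement error
  estimates, no rotational ambiguity exploration).
- The published aggregate survey statistics are internally inconsistent
  at the rounding level (the seven carcinogenic congener means sum to
  5.74 µg/kg against a published Σ7 aggregate of 5.52); the package
  stores both and the compositional summaries state which is used.
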