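# Methods

## Panel model

An observation is one region in one year: population P (persons, > 0), land
area A (km², > 0), per-capita GDP g (currency/person, > 0) and a non-negative
value per configured resource indicator. The panel is wide (one indicator per
column), mirroring yearbook extracts; long tables are pivoted with
`panel_from_long`. One record per (region, year) is enforced at ingest, as is
strict positivity of P, A and g — a zero-area or zero-population region would
make the agglomeration degrees infinite, so such rows are rejected up front
rather than propagated.

Parent-region totals (HRₙ, Pₙ, Aₙ) default to column sums over the observed
regions; they can be supplied explicitly (e.g. when the regions are a subset
of a larger parent), in which case they replace the sums and must be strictly
positive. Reach aggregation sums population, area and every indicator over
group members and takes the population-weighted mean of per-capita GDP; the
source panel's totals are frozen into the aggregate so group-level
agglomeration degrees are judged against the same parent as region-level
ones. Aggregation is invariant to row order and conserves all totals.

Units are taken as given (counts, persons, billion yuan). No conversion is
performed: every downstream statistic is either scale-invariant (HRAD,
HRAD/PAD, CI, TOPSIS closeness under vector normalisation) or explicitly
normalised (entropy proportions).

## Agglomeration degrees

HRAD and PAD are share ratios; the percentage factors in their textbook
definitions cancel and are not applied. The fairness ratio HRAD/PAD is
computed from the degrees but equals the per-capita ratio
(HRᵢ/Pᵢ)/(HRₙ/Pₙ) algebraically; the test suite verifies that identity on
random panels. Two conservation identities hold by construction and are
enforced in tests: Σᵢ HRADᵢ·(Aᵢ/Aₙ) = 1 and Σᵢ PADᵢ·(Aᵢ/Aₙ) = 1 whenever the
regions partition the parent.

Rankings are descending ordinal ranks ("Sort" columns): rank 1 for the
largest value, ties broken by panel row order. Competition ranking would be
equally defensible; ordinal ranking was chosen because it is stable and
reproducible, and the published tables this mirrors show no ties.

## Entropy weighting

Column proportions p_ij = x_ij / Σᵢ x_ij feed the Shannon entropy
(via `scipy.stats.entropy`, which applies the 0·ln 0 = 0 convention),
normalised by ln n where n is the number of alternatives *in the scored
block* — provinces and reaches are scored as separate blocks with their own
n, which is why reach-level entropies live on a very different scale than
provincial ones. Utilities d = 1 − e and weights w = d/Σd. A column with
identical values carries no information (e = 1, w = 0); if *every* column is
uniform the weights are undefined and a degenerate-matrix error is raised
rather than returning an arbitrary vector. An optional min-max pre-scaling
flag exists for matrices mixing units; the default (plain column
proportions) is the standard entropy-weight construction and is the right
choice for agglomeration-degree inputs, which are already dimensionless.

## TOPSIS

Vector (root-sum-square) normalisation, the classical choice; weighted
columns; positive/negative ideals are the column max/min for benefit
criteria (swapped for cost criteria — all ten defaults are benefit-type,
since the score measures agglomeration level); Euclidean distances; relative
closeness C = D⁻/(D⁺ + D⁻); descending ordinal ranks. The scored matrix
defaults to HRAD values per region (composite agglomeration level); raw
indicator values are available via `matrix="raw"`. Closeness is invariant to
per-column rescaling of the raw inputs, checked by test. A matrix whose rows
all coincide with both ideals (all columns constant) raises a degenerate
error. The full entropy→TOPSIS chain is cross-checked to 1e-12 against an
independently coded loop implementation on random 11×10 matrices.

## Concentration curve and index

Regions are sorted by ascending per-capita GDP (ties broken by panel row
order, so the curve is deterministic for a given file). The X axis is the
cumulative *population* share, not the cumulative region count; Y is the
cumulative resource share; the origin (0,0) is prepended so the trapezoid
sum S = ½Σ(Yᵢ+Yᵢ₊₁)(Xᵢ₊₁−Xᵢ) runs over all n segments. CI = 2·(0.5 − S):
a curve above the diagonal (resource concentrated in poorer regions) has
S > ½ and CI < 0; pro-rich allocation gives CI > 0. For grouped data this
trapezoid construction is algebraically identical to the covariance form
CI = (2/μ)·Σᵢ sᵢμᵢ(Rᵢ−½) with fractional ranks Rᵢ; the equivalence is
verified to 1e-9 on a thousand random panels, and reversal of the economic
ordering maps CI → −CI exactly. No standard errors, dominance tests or
bounded-variable corrections (Erreygers/Wagstaff) are computed: the
resources here are unbounded counts.

## Synthetic generator

The generator emulates a yearbook panel's statistical structure:

| parameter | default | meaning |
|---|---|---|
| `area_lognorm` | (ln 1.5e5, 0.9) | heavy-tailed provincial land areas, km² |
| `pop_density_lognorm` | (ln 300, 0.5) | persons/km²; population = area × density |
| `gdp_lognorm` | (ln 6e4, 0.35) | per-capita GDP, yuan |
| `base_rate` | per indicator | resource per capita at mean economic level |
| `gamma` | 0 | economic-gradient exponent of the allocation |
| `noise_cv` | 0 | CV of unit-mean multiplicative lognormal noise |
| `trend` | 1.0 | year-on-year multiplicative drift |

value[i,t] = base_rate · Pᵢ · (gᵢ/ḡ)^γ · trend^(t−t₀) · ε, with ḡ the
unweighted cross-region mean GDP. Areas, populations and GDP are drawn once
and held fixed across years — real short panels have essentially stable
cross-sectional geometry — so only noise and trend vary in time. Draws are
ordered (areas, densities, GDP, then noise indicator-by-indicator and
year-by-year) so a given seed fully fixes the panel.

The `yeb-like` preset models an 11-region economic belt in three contiguous
reaches (4/3/4) with GDP sorted descending (downstream richest). Its γ values
are a *sign-pattern fixture* for the observed 2019 allocation: negative for
health institutions (−0.6), TCM institutions (−0.3) and grassroots beds
(−0.4); positive for the rest, smallest for primary health technicians (0.1)
and medical beds (0.15), largest for general practitioners (1.4); noise CV
0.05, trend 1.02. Magnitudes were set once from the qualitative published
ordering, not calibrated to reproduce published index values.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions, migration or urbanisation dynamics, policy shocks,
reporting artefacts, and any correlation between γ and region size. Passing
tests on synthetic panels therefore demonstrate the correctness and
statistical behaviour of the estimators, not claims about any real region's
data.

Two degenerate limits are worth distinguishing. With γ = 0 and no noise,
resources are exactly proportional to population, forcing CI = 0 and
fairness ratio = 1 — but the HRAD decision matrix then equals the PAD vector
in every column, which is dispersed, so entropy weighting legitimately
returns equal weights. Only when the regions are additionally *identical*
(all lognormal sigmas 0) does the matrix become constant and the degenerate
error fire. Both regimes are covered by tests.

## Numerical conventions

- Published-table mirroring uses half-away-from-zero rounding (3 decimals by
  default, matching the convention of the provincial tables); all internal
  computation is double precision and unrounded. Rounding operates on the
  shortest decimal representation of the float so that values printing as
  exact halves round up.
- Re-deriving published cells from published (already rounded) inputs can
  disagree with the published result by one unit in the last place; the
  acceptance tests allow ±0.002 for such cells and are exact elsewhere.
- Ranks, GDP sort order and group order all tie-break by panel row order
  (stable sorts throughout), making every output deterministic for a given
  input file and config.
- The pipeline computes all tables before writing any, so a failed stage
  (reported with its stage name) leaves no partial outputs; the run manifest
  records the input hash, seed, years, row counts and library versions.

## Problem sizes

The verification suite uses the study's natural scale — 11 regions, 3
reaches, 7 years — for fixtures and the preset; cross-checks run on 1,000
random panels of 2–11 regions, and the gradient-recovery sweep uses 500
replicate seeds per γ ∈ {−0.5, 0, 0.5, 1}, sizes at which the Monte-Carlo
standard error of the γ = 0 mean CI is ≈ 4·10⁻⁴.
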