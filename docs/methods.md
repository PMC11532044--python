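# Methods

This note documents the model implemented by `fiscalfood`, its
assumptions, the defaults and why they were chosen, and what the synthetic
inputs do and do not emulate.

## Scope and framing

The model is a *short-term, steady-state* comparative risk assessment: a
one-shot price change moves the food basket to a new equilibrium, exposures
and BMI settle at their new steady-state values, and one year of disease
incidence, DALYs, footprints and costs is compared against the no-tax
baseline for a fixed reference population of one million adults aged 25+.
There is no multi-state lifetable, no time lag between exposure change and
risk change, no disease remission dynamics, and no discounting (a one-year
horizon makes it moot). Effects of this kind plausibly attenuate over
time; the model makes no claim beyond the short run.

## Demand response

The default response rule is linear in the price change,
ΔQᵢ/Qᵢ = Σⱼ eᵢⱼ·ΔPⱼ/Pⱼ, where eᵢⱼ are point elasticities from an
externally estimated demand system (elasticities are *inputs* here; the
package does not estimate them). The linear rule matches how point
elasticities are usually applied to a one-shot price change and makes the
calibration back-solve exact. A multiplicative alternative,
Q*/Q = Πⱼ(1+ΔPⱼ/Pⱼ)^eᵢⱼ, is available via `response="loglog"` for
sensitivity exploration; the two agree to first order.

Pass-through defaults to 1.0 (the consumer bears the full tax; supply is
perfectly elastic, producer prices unchanged). Quantities are floored at
zero without renormalisation; the floor breaks linearity, so a warning is
logged when it binds.

Substitution is evaluated on the population-mean basket (group quantities
per AME), not household by household; the household-level API
(`per_ame_intake`) exists and is tested, and aggregating before or after
the linear response is equivalent when every household faces the same
elasticity matrix — which is the only case the inputs can express.

AME coefficients (energy needs relative to a moderately active man aged
18–30, who scores exactly 1.0) are an input table; the packaged default
(`ame_coefficients_synthetic.csv`) is a synthetic stand-in with the usual
qualitative structure (children lower, women ~0.72–0.85, older adults
slightly lower).

## Exposure and BMI

Five risk factors: sugar, SSB, SFA and TFA intake (g/day) and BMI (kg/m²).
Dietary exposures are linear in the consumed basket via per-100 g
composition coefficients; SSB exposure is the consumed grams of the SSB
group itself.

BMI uses the steady-state energy-balance rule ΔBMI = (ΔE/ρ)/h² with
ρ = 94 kJ/day per kg (≈22.5 kcal/day per kg, the common rule of thumb for
the sustained intake change per kilogram of steady-state body weight).
The full dynamic energy-balance ODE is deliberately out of scope: for a
permanent intake shift evaluated at equilibrium the steady-state rule is
the limit of the dynamic model, and height and physical activity are held
fixed. ρ is configurable.

The counterfactual BMI is floored (default 15 kg/m²) as a safety bound so
extreme synthetic energy shifts cannot produce biologically impossible
BMIs; the floor never lifts a person whose *baseline* BMI is already below
it, so a null scenario is an exact fixed point. Person-level intake
heterogeneity is available (`intake_cv`, a unit-mean log-normal multiplier,
default 0) because population-mean percent changes are invariant to it; it
matters only for PIF curvature.

## Health impact

RR(M) = exp(ln RRₓ · M/x) scales a tabulated per-increment relative risk
to arbitrary exposure; PIF = 1 − ΣRR(M*ᵢ)/ΣRR(Mᵢ) over individuals within
each age-sex stratum. BMI enters as exposure above a theoretical-minimum-
risk BMI (default 22 kg/m², configurable) — applying a per-unit RR from
zero BMI would be meaningless.

PIFs from several risk factors acting on one disease combine as
1 − Π(1 − PIFᵣ), the standard multiplicative rule under independence of
relative risks. This overstates joint effects when pathways overlap (the
BMI pathway partly mediates the dietary ones); with the small PIFs
produced here the overlap error is second-order. Negative PIFs (exposure
*increases* under substitution) are allowed and produce negative averted
burden — required to capture substitution harms, e.g. SFA rising under an
SSB tax.

The risk-factor → disease mapping ships as editable data
(`risk_outcome_map.yaml`), defaulting to: BMI → all six diseases; sugar →
type-2 diabetes; SSB → type-2 diabetes and ischemic heart disease;
SFA/TFA → ischemic heart disease and ischemic stroke.

PIFs estimated on the simulated sample (default 10,000 persons) are
applied to the full stratum populations (one million by default);
incidence percent changes are standardised with the population's own
age-sex structure as weights.

## Environment and costs

Footprints are computed on *purchased* (pre-waste) quantities — the
coefficients describe production-side burdens, which include wasted food;
waste adjustment exists only to estimate intake. Green/blue/grey water is
collapsed into one L/kg coefficient. Footprint changes are reported per
AME-day; percent changes are scale-free.

The cost ledger (billion 2020 Rials per year, costs positive / savings
negative):

* **Household**: the changed basket valued at pre-tax prices — the tax
  payment is a household→government transfer that cancels out of the
  societal ledger. Consumer-price valuation is available via
  `use_posttax_prices` for anyone who wants to book the transfer
  explicitly on both sides.
* **Water/carbon**: footprint deltas priced per m³ (agricultural price by
  default; accounting and industrial variants for sensitivity) and at the
  social cost of carbon.
* **Healthcare**: averted incident cases × per-case treatment cost ×
  CPI inflator, entering negatively.

Scaling from per-AME-day to the reference population uses an explicit
factor (population × 365 AME-days/year, treating one adult as one AME);
the factor is a parameter so a person-day reading is equally reproducible.

ICER = total cost / DALYs averted, compared with a threshold of one GDP
per capita per DALY (0.61 BR, configurable). A scenario with positive
cost and negative health gain is flagged dominated. Two-decimal rounding
happens only in the reporting layer.

## Uncertainty and sensitivity

Per draw: elasticity cells get additive normal noise (diagonal clipped to
stay negative, preserving matrix validity), each RR is redrawn log-normally
with its own `log_sd`, and each monetary coefficient is scaled by a
truncated-at-zero normal factor; then the identical deterministic pipeline
reruns. Intervals are 2.5th/97.5th percentiles — nonparametric, because
the ICER distribution is skewed — and the ICER interval is the percentile
interval of per-draw ICERs (paired ratios), never a ratio of interval
endpoints. The simulated population is built once per analysis and reused
across draws (anthropometry is not a perturbed input), so a fixed seed
gives bit-identical intervals. Default 1,000 draws; at 10,000 persons a
scenario completes in seconds on one core.

The sensitivity suite reruns each scenario under: A — all rates 10%; B —
all rates 50%; C — accounting water price; D — industrial water price.
Because water costs enter the ledger linearly, a higher water price lowers
the ICER of scenarios with net water savings and raises it where
substitution increases water use.

## Synthetic inputs

`generate_bundle` emulates the statistical structure the analysis assumes:
log-normal purchase quantities parameterised by mean and CV (expenditure
data are right-skewed; log-normal guarantees positivity), own-price
elasticities drawn negative with cross terms clipped below the own
response, RR point values above 1 with configurable log-normal
uncertainty, and disease rates rising geometrically with 5-year age band
(25–29 through 80+, both sexes, counts declining with age and summing
exactly to the configured population). One seed drives all sub-generators
in fixed order, so bundles are bit-identical per config and partial
regeneration is deliberately impossible.

`calibration_bundle` is the fixed reference configuration: its elasticity
matrix is *back-solved* under the linear demand rule so that the three
reference scenarios reproduce stated own-group exposure responses exactly
(25% sugar-and-sweets tax → −10.76% sugar; 30% SSB tax → −14.26% SSB; 30%
hydrogenated-oil tax → −7.82% SFA), with cross terms encoding the observed
substitution pattern (an SSB tax raising red meat, fruit, vegetable and
legume purchases, which drives its *positive* water/carbon footprint
change). To keep the back-solve exact, each marker nutrient lives in a
single group: sugar only in the sugar-and-sweets group, SFA/TFA only in
the fats group, and the calibration SSB group carries no sugar
coefficient. This is a deliberate identification device, not a claim
about food composition.

What the synthetic inputs do **not** emulate: survey sampling weights and
design, geographic stratification, the full breadth of a real household
food basket (8 groups here), real anthropometry, country-specific GBD
rates, or empirically estimated cross-elasticity magnitudes beyond the
encoded cells. One visible consequence: with this pruned basket, household
food spending *falls* under every tax, so ledger totals are negative and
ICERs are cost-saving — against a full empirical basket with richer
substitution, household costs can be positive and ICERs positive.
Passing tests therefore demonstrate the correctness and internal
consistency of the modelling chain under controlled conditions, not the
magnitudes any real population would exhibit.

## Numerical choices

* Percentile intervals via `numpy.percentile` (linear interpolation).
* Stratum counts rescale by largest-remainder rounding, so simulated
  samples match stratum proportions exactly at any size.
* Heights/weights from per-stratum truncated normals (1.2–2.2 m,
  30–200 kg) via `scipy.stats.truncnorm`; SD 0 collapses to the mean.
* PIFs are computed with vectorised `exp` sums; an independent scalar-loop
  oracle in the test suite agrees to ≥12 significant digits on 1,000
  random instances.
* Ledger totals are exact component sums (no internal rounding); ICER of a
  zero-DALY run is undefined and surfaces as an error (library) or a null
  result (pipeline).
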