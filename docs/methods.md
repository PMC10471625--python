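# Methods

This note documents the model implemented by `emfarm`, its parameter
defaults, the numerical conventions, and the design decisions taken where
the method left genuine choices open. It is the package's own account of
its science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Emergy accounting model

The unit of account is the solar emjoule (sej): the available solar energy
directly and indirectly required to produce a flow. Three conversions are
used depending on how a resource is quantified — transformity (sej/J),
specific emergy (sej/g) and the em-euro ratio (sej/€) for flows that exist
only as money (veterinary services, depreciation, CAP payments). A fourth
unit class, sej per work-unit year, covers labour, which the farm schema
carries in work units rather than euro.

**Baseline homogenisation.** Published UEVs are tied to the global emergy
baseline (GEB) under which they were derived and scale linearly with it.
Every entry of the UEV table records its source baseline; before any
conversion all entries are rescaled to one working baseline
(`uev × target/source`). The default working baseline is 12.0 × 10²⁴
sej/yr; the shipped table mixes entries published under 15.83 × 10²⁴ and
12.0 × 10²⁴ sej/yr, which is the situation the rescaling step exists for.

**Renewability split.** Each UEV entry carries a renewability factor in
[0, 1]; a flow of total emergy *T* contributes *rf·T* renewable and
*(1−rf)·T* non-renewable emergy. Factors in the shipped table are package
defaults with a documented source note per entry (e.g. 0 for diesel, 0.25
for grid electricity, 0.25–0.40 for purchased feeds, 0.10 for monetary
flows through the national economy); the table is user-replaceable.

**Same-origin rule.** Solar radiation, wind, rain chemical potential and
evapotranspiration are co-derived from the same solar source; summing them
double-counts it, so only the flow with the highest emergy enters the
account. Ties break by alphabetical resource name — a fixed, documented
order chosen for determinism, exercised only in degenerate equal-flow
inputs. Which flow wins is an outcome of the climate record and the
transformities, not a rule: with the default climate (rainfall 1.0 m/yr,
ET 0.55 m/yr, equal rain/ET transformities) rain chemical potential wins.

**Natural local flows.** Available-energy forms over an area A (m²):
solar A·insolation·(1−albedo); rain chemical A·rainfall·ρ·G and
evapotranspiration A·ET·ρ·G with water density ρ = 10⁶ g/m³ and Gibbs free
energy of rain G = 4.94 J/g; wind A·(dissipated near-surface kinetic energy
density); soil erosion A·(erosion rate)·(organic fraction)·(energy content
of organic matter, 22 604 J/g). Soil erosion is always category N: soil is
consumed faster than it renews. The default climate record describes a
temperate mid-mountain study area; a single record serves all farms unless
per-valley records are configured.

**Services netting.** S = em€·(CAP payments − taxes paid). The net flow is
floored at zero with a warning if taxes exceed subsidies, preserving the
non-negativity of the account components. Labour is classified as a
purchased flow (the schema carries a single labour field; hired and family
labour are not separated).

## Grazing allocation

For each grazing area the herd's area is LU/stocking rate (0.2 LU/ha on
valley meadows and forests, 1.2 LU/ha on mountain pastures). The full-NPP
emergy *E* of that area is the winning solar-origin flow over it — in
emergy algebra, a product (pasture NPP) carries the emergy of the flows
that drive it. The consumption-based allocation is

    allocated = E · (grazing days / 365) · 0.50 · consumed fraction

with ANPP/NPP = 0.50 on both areas and consumed fractions 0.65
(meadows/forests) and 0.40 (mountain). The farm's natural-pasture emergy is
the sum over the two areas. The allocated amount never exceeds *E*, is
strictly increasing in grazing days and in each fraction, and is treated as
fully renewable since *E* is solar-derived.

The **standard baseline** allocates the full annual *E* of every area the
calendar actually uses (an area with zero grazing days is not part of the
farm's system). The per-farm reduction 1 − allocated/standard is invariant
to the magnitude of *E*: it equals a weighted mean of
(days/365)·0.5·consumed across the two areas, with weights proportional to
the grazed areas (6:1 meadows/forests:mountain when both are used, from the
stocking-rate ratio). Because the meadows/forests area dominates the
baseline while mountain days carry the smaller consumed fraction, the
reduction under the default calendar split sits near 87 % (computed by the
acceptance script); it falls toward 78 % only when grazing concentrates
entirely on meadows and forests.

The allocation equation also circulates in a divided form (E divided by the
product of the three factors). That form is dimensionally inconsistent and
would award more emergy to farms that graze less, so the multiplicative
form is the default; the divided form is available behind
`division_form=True` / the `division_form_audit` run mode for audit, and
the run log records which interpretation a run used. The organic-matter
return flow from livestock to pastures is real but unquantified in the
source framework and is excluded from the account.

## Indicators and classification

Formulas as in the README. Conventions:

* Division by zero yields `inf` plus a flag in `IndicatorSet.nonfinite`,
  never an exception; a farm with Y = 0 (an empty system) is an error.
* ESI is always the composite of the alternative EYR and ELR (renewable
  fractions of P and S credited to the renewable side); reported EYR and
  ELR are the classical forms, and both variants are kept on the object.
* Boundary inclusivity follows the published inequalities verbatim
  (EYR ≤ 2, EIR ≥ 1, EER > 1, ELR ≥ 2, ESI ≤ 1, 1 ≤ ESI ≤ 5). The overlap
  at ESI = 1 between the unsustainable and short-term bands resolves to
  unsustainable.
* EER's denominator is product-sale income only (not subsidies): it
  compares the emergy delivered with the money actually paid for the
  product.
* Cohort summaries use sample SD (n−1), linear-interpolation quartiles and
  Tukey 1.5×IQR whiskers/outliers; the two farm types are never pooled
  because their outputs differ.

## Synthetic cohort generator

The generator emulates the cohort structure of a two-type survey (40 weaner
and 10 weaner-finisher farms by default):

* **Marginals.** Strictly positive, right-skewed variables (area, herd LU,
  labour, income, CAP, variable costs) are lognormal matched to the
  calibrated mean/SD; grazing days are normal truncated to [0, 366]
  (truncation shifts the mean by ≈0.5 %, inside the 2 % recovery
  tolerance). Distribution families are package choices: only means and
  SDs are published.
* **Dependence.** A Gaussian copula links herd size, area, income and CAP
  payments at a Spearman target of 0.6 (configurable, 0 for independence),
  converted to the Gaussian correlation via ρ = 2 sin(πρₛ/6).
* **Herd decomposition.** LU splits into integer head counts with per-cow
  ratios (0.02 bulls, 0.20 heifers, 0.85 calves → 1.50 LU per cow); the
  farm's effective LU is always recomputed from the integer herd.
* **Calendar split.** One third of the drawn grazing days go to mountain
  pastures (the summer leg of the transhumant year), the rest to valley
  meadows/forests; configurable.
* **Taxes.** Drawn CAP payments times a fixed type-specific ratio (≈2.1 %
  and ≈1.4 %), matching the relative magnitudes of the two service
  components in the target composition.
* **Inventory back-solve.** The target composition assigns every purchased
  item a share sᵢ of total emergy and the remaining anchor share a to
  natural locals + net services + labour combined. After drawing the
  structure, the generator computes the anchor emergy with the same
  functions the pipeline uses and sets Y_ref = anchor/a and
  qᵢ = sᵢ·Y_ref/UEVᵢ. The assembled farm's pipeline total then equals
  Y_ref exactly and each item lands exactly on its target share — which is
  what makes the concentrates-share acceptance check a genuine end-to-end
  identity rather than a Monte-Carlo estimate. Item prices and variable
  costs do not constrain quantities; variable costs are carried in the
  economic record only.

What the generator does **not** emulate: real farms' joint distribution
beyond the four-variable copula; per-farm day splits (fixed fraction);
weather variation across farms; and any control over how the anchor share
divides between natural locals, services and labour — that split follows
from the drawn structure and the default climate, so cohort-level shares of
those three groups (and all downstream indicator levels) should be read as
properties of the synthetic conditions, not of any surveyed population.
Passing tests demonstrate the accounting arithmetic, the allocation
behaviour and the calibration recovery; they do not validate field data.

## Numerical conventions

* All sej identity checks at 1e-9 relative tolerance.
* Farm CSVs are written with `%.17g` and read with round-trip float
  parsing, so read/write round trips are bit-exact; the UEV table is parsed
  the same way.
* Runs are deterministic given config and inputs; outputs are
  byte-identical across repeated runs, and the run metadata sidecar stores
  a config hash instead of timestamps to keep them so.
* Problem sizes: acceptance uses 50-farm cohorts over 10 seeds for the
  allocation comparison, 1000 farms for the end-to-end share check, 4000
  for calibration recovery, 1000 random accounts for the indicator oracle
  and 500 perturbations for the monotonicity property — sizes chosen so the
  whole suite runs in seconds on one CPU.

## Known limitations

* UEVs, renewability factors, em€ (1.1 × 10¹² sej/€) and the climate record
  are literature-magnitude package defaults, not site measurements; results
  scale directly with them.
* The consumption allocation treats per-ha emergy as identical across areas
  (one climate record), so the area weights in the allocated/standard ratio
  are fixed by the stocking rates.
* No emergy algebra for co-products or upstream process networks: UEVs are
  taken as given.
* Ecosystem services beyond grazing, multi-year dynamics and survey
  ingestion are out of scope.
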