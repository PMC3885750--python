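# Methods

## Model overview

The package implements a one-stage, person-level Monte Carlo exposure
model. One replicate is one simulated individual; 10,000 replications per
scenario is the default. The urban and rural sub-populations are simulated
separately, each against its own baseline (B-u, B-r), because their
dominant risk factors differ (solid-fuel cooking is rural).

Per replicate the chain is: sample demographics, household and workplace
environments and a time-activity budget → draw a seasonal outdoor
concentration field → solve the indoor single-zone steady state per
congener and phase → integrate concentration × time × ventilation over the
microenvironments and the four seasons → standardize to B[a]Peq with TEFs →
convert the lifetime concentration to lung-cancer relative risk and
aggregate to PAF/PIF.

## Outdoor concentrations

Seasonal medians and SDs for the 16 congeners (Beijing measurement
summaries, 2005–2007) ship as a CSV. Each cell is fitted with a lognormal:
`mu = ln(median)` and, with `w = exp(sigma²)`,
`w² − w − (sd/median)² = 0` solved in closed form. Zero-median cells are
point masses at zero; zero-SD cells at the median. Environmental
concentration data of this kind are strictly positive with SD ≫ median,
which rules out a normal law.

Within a replicate, congeners within a season share one lognormal quantile
(perfect rank correlation) by default, reflecting their common combustion
origin; `correlated_outdoor: false` switches to independent draws. Whether
the original application sampled jointly or independently is not
recoverable; the switch makes the assumption explicit.

## Indoor mass balance

Well-mixed single zone, linear instantaneous equilibrium, emissions
averaged over 24 h. Per phase: loss = a + k + CADR/V; outdoor-origin
= P·a·C_out/loss; indoor-origin = (E/V)/loss. Gas phase: P = 1, k = 0,
cleaner ineffective. Particle phase: penetration from Table defaults
(0.90 ± 0.06), deposition k = 0.2 h⁻¹ (not reported; configurable), and
the particle-bound fraction per congener is an assumption shipped as a CSV
(1.0 for the five-ring and heavier congeners, 0.5 for chrysene and
benz[a]anthracene, 0.05 for the lighter ones). The phase split only
matters for the deposition and cleaner pathways; total airborne
concentrations are insensitive to it when those sinks are off.

The indoor cleaner's CADR (134 m³/h market average) runs 16 h/day and is
time-averaged to `134·16/24 ≈ 89.33 m³/h`, consistent with the
24-h-averaged emission convention — sinks and sources must share the
averaging window.

Emission factors (ng per cigarette, ng per kg fuel, by congener and phase)
are **not measured inputs**: no values are published alongside the
concentration table. The packaged CSV holds documented placeholder
profiles whose B[a]Peq magnitudes (≈0.1 µg/cigarette, ≈2.5 µg/kg wood and
crop residue, ≈6 µg/kg coal, ≈0.2 µg/kg LPG, effective-indoor) were
calibrated once, before any tests were frozen, so that the packaged
defaults reproduce the published *relative* importance of indoor sources —
i.e. the qualitative intervention ordering (atmospheric cleaning > indoor
cleaner > clean fuel > exhaust > smoking ban) and near-nil smoking impact.
They are deliberately smaller than stack-measured fuel emission factors:
they represent the fraction that reaches the living zone. All quantitative
conclusions that depend on their absolute values should be treated as
illustrative; users with a measured inventory should replace the CSV.

## Population and time-activity

Demographic constants: 84% urban, 51.1% male, 31.1% smokers, 72% employed,
9% school-age. Parameter distributions (per region): infiltration ACH
0.31 ± 0.23 urban / 0.59 ± 0.47 rural, floor area 53.4 ± 24.6 /
128.9 ± 59.3 m², penetration 0.90 ± 0.06, work/school time 5.45 ± 3.01 h,
household smoking 9 ± 19 cigarettes/day, rural wood/crop use
4.00 ± 2.61 kg/day. Families are not reported; roughly symmetric physical
quantities use normals truncated at physical bounds, heavy-tailed ones
(SD > mean: smoking, fuel) use moment-matched lognormals. Truncation
shifts means above the nominal central value (e.g. rural ACH truncated at
~0 has mean ≈0.69); tests therefore check sample means against each
configured distribution's analytic mean.

Choices where the sources are silent: ceiling height 2.7 m (typical
Chinese residential construction); home time 16 ± 2 h/day (16 h is the
stated typical time at home; the SD is a modelling choice); commuting is
folded into "outdoor"; daily inhalation 16 m³ allocated by activity
multipliers home 0.8× / work 1.0× / outdoor 1.5× of the hourly mean;
workplace as a simpler zone (ACH 1.0 h⁻¹, 30 m³ per occupant, no cooking,
smoking unless banned — ban fraction 0.30); rural coal quantity
2.0 ± 1.5 kg/day among the coal-using households (11% of the total
population, i.e. 0.6875 of rural households), burned with chimneys
(emission-remaining factor 0.10); urban cooking on LPG 0.4 ± 0.2 kg/day
with 30% regular hood users at ERF 0.50. Non-employed individuals have
their drawn work hours reallocated to home. Time budgets close to 24 h
exactly by construction.

The individual smoker flag (31.1%) is demographic; household environmental
tobacco smoke uses the household-level quantity, zeroed under a home
smoking ban (20% urban, 10% rural households).

## Risk model

`RR = URR^(C/100)` with C in µg/m³·year of lifetime B[a]Peq exposure
(time-weighted concentration × 70 years default). This power form is the
only standard one for which RR at the 100 µg/m³·year reference equals the
URR exactly and for which PAFs re-evaluated at alternative URRs remain
mutually consistent; a linear excess-risk form fails that consistency
check. RR is computed per individual and then averaged (arithmetic mean);
PAF = (R̄R−1)/R̄R; PIF = (R̄R_b−R̄R_i)/R̄R_b. URR default 4.49 (Chinese
coal-smoke cohort); variants ±20% and 1.30 (Asian populations) are
reported side by side. The risk metric uses concentration-years, not
inhaled dose, because the URR is defined against a concentration-years
exposure; the annual dose is reported separately.

## Scenario engine and common random numbers

Scenarios are declarative edit lists applied to the *sampled* state, so a
fixed seed pins the entire baseline draw and scenario pairs differ only
through the edit. Every deviate an edit might need (e.g. the clean-fuel
selection lottery) is drawn at sampling time for every individual.
Consequences: the WHO rescale hits its per-season B[a]Peq target
(1.2/0.381 ≈ 3.15 ng/m³) exactly per replicate; exhaust scenarios cap the
cooking ERF at min(current, value) so chimney households are never made
worse and the Ex-20 ≤ Ex-50 ≤ Ex-80 ≤ baseline ordering holds pathwise;
fuel shifts replace solid-fuel mass with LPG at equal fuel energy content
(16/23/46 MJ/kg wood/coal/LPG, configurable).

## Numerical choices

Quantiles use linear interpolation between order statistics (`numpy`
default). Exposure-pattern dominance ties break by the fixed priority
OUT-in > IN-in > OUT-out (ties are measure-zero under continuous
sampling). Zero-exposure individuals report all-zero pattern shares.
Households with ACH ≤ 0 are rejected (the steady state is undefined); the
default ACH truncation bound is 0.01 h⁻¹. I/O ratios are NaN when the
outdoor B[a]Peq of a draw is zero. Lognormal moment fits guard the
SD/mean ratio against overflow. Sensitivity shifts move a distribution's
central value by ±1 SD, leave its SD intact, clip shifted medians of the
outdoor table at zero (a zero median is a point mass), and re-run under
the unchanged seed.

## What the synthetic population does and does not emulate

It reproduces the published demographic fractions, the parameter table's
central values and SDs, the baseline fuel/ventilation prevalences and the
urban/rural contrast. It does **not** model household composition, spatial
geography, seasonal time-activity variation, behavioural feedback of I/O
ratios on time allocation, gas–particle repartitioning, dermal/ingestion
pathways, acute-disease risk, or two-stage variability/uncertainty
separation. Passing tests therefore validate the model mechanics and the
stated qualitative findings under these synthetic conditions — not
absolute exposure or risk levels for any real population; the absolute
PAFs depend on the unpublished emission and survey inventory of the
original application and come out somewhat lower here (rural baseline
≈2.4% vs the published 3.63%).

## Problem sizes

Default runs use 10,000 replications per scenario (all 15 scenarios on
shared cohorts in well under a minute on one core). The test suite runs
its end-to-end checks at the same n = 10,000 and its unit/property checks
at a few hundred replicates; the sensitivity sweep default is n = 2,000,
chosen as ample for the ±SD contrasts under common random numbers.
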