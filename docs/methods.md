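# Methods

`siclimate` models the coupled global carbon and silica cycles around the
end-Permian mass extinction, with the hypothesis under study being that the
collapse of the marine biological silica factory enhanced reverse weathering
(marine authigenic clay formation) enough to recycle CO₂ within the
ocean–atmosphere system and sustain multi-million-year warmth. This note
documents the model equations, the numerical choices, the calibration, and
what the synthetic-data closed loop does and does not demonstrate.

## Model structure

The ocean is two well-mixed boxes — surface (top 100 m) and deep — plus an
atmosphere. Prognostic tracers are atmospheric CO₂ (carried as carbon mass,
1 ppm ≡ 1.77×10¹⁴ mol C), DIC, total alkalinity (TA) and dissolved silicon
(DSi) in both boxes, and ¹³C in all three carbon reservoirs. ¹³C is carried
as the ratio-weighted mass r·M with r = 1 + δ¹³C/1000, which makes the
isotope equations linear and exactly conservative. Three additional states
co-integrate the cumulative net inputs of C, Si and ¹³C so that mass
conservation can be verified against the reservoir change without quadrature
error; runs maintain both budgets to better than 10⁻⁶ relative (typically
10⁻¹³).

### Carbonate chemistry and climate

Speciation (pH, CO₂(aq), HCO₃⁻, CO₃²⁻, Ω_calcite) is solved from (DIC, TA)
with a single pinned constant set: Lueker et al. (2000) K₁/K₂, Dickson
(1990) borate, Millero (1995) water, Weiss (1974) CO₂ solubility, Mucci
(1983) calcite, all total scale, with fixed seawater density 1025 kg m⁻³,
boron proportional to salinity, and calcium configurable (default modern
10.28 mmol kg⁻¹). The root in [H⁺] is found by damped Newton iteration
warm-started from the previous integrator step, with a safeguarded Brent
fallback on pH ∈ [2, 12]; no root in that window raises a
degenerate-chemistry error naming the offending (DIC, TA). Tests verify the
solver against an independent million-point pH grid search.

Climate couples to the model only through pCO₂: ΔT = S·log₂(pCO₂/pCO₂_ref)
with equilibrium climate sensitivity S (°C per doubling, sampled 2–5).
Temperatures used in the equilibrium constants are the background surface
temperature (20 °C modern / 22 °C Permian at the weathering reference pCO₂)
plus the anomaly; the deep box sits a fixed 16 °C below the surface,
clamped to the validity range of the constants. Reported temperature
anomalies are relative to each run's own spin-up state.

Air–sea CO₂ exchange is linear in the pCO₂ disequilibrium with a piston
velocity (default 1752 m yr⁻¹ ≈ 20 cm h⁻¹). The ¹³C exchange uses gross
invasion/evasion fluxes with the kinetic factor 0.99912 and the
temperature-dependent equilibrium fractionations of Zhang et al. (1995),
weighted over the carbonate species for the DIC–gas factor; the net ¹³C
flux vanishes exactly at joint chemical and isotopic equilibrium.

### Flux laws

Weathering follows the canonical power laws
F = F⁰·(pCO₂/pCO₂ᶜ)ⁿ with n_si ∈ 0.2–0.5 and n_carb ∈ 0.1–0.3 and
F⁰_silw equal to the background volcanic degassing (5 Tmol yr⁻¹).
Terrestrial SiO₂ (quartz) weathering is 19% of the silicate flux and
delivers DSi only. Constant silica inputs (dust 0.5, hydrothermal 1.7,
marine sediment weathering 1.9, groundwater 0.7 Tmol Si yr⁻¹) are central
values of the modern marine silica budget.

Biogenic silica production is Michaelis–Menten in surface DSi
(V_max = 1.74, K_m = 74.48 µM) scaled by k_bSi (2.7–3.2×10¹⁴ modern;
10¹⁰–7×10¹³ sampled log-uniformly for the Permian, where sponges and
radiolarians were the only silicifiers). Opal dissolves in each reservoir
as F_in·(1 − [Si]/ς)^ρ with solubility ς = 0.9 mM, ρ = 5.5 in the water
column and 0.4 at the sediment interface; the undissolved sediment flux is
buried.

Authigenic clay formation (reverse weathering) is
F_rw = (β + α)(Ω_rw − o), clamped at zero below the offset o, where
α sums the constant Si inputs plus volcanic-equivalent weathering
(9.8 Tmol yr⁻¹), and β couples clay formation to the biogenic silica rain
reaching the sediment via the modern ratio F_rw/F_bSi_sed (sampled
0.022–0.099). The saturation state is Ω = ([X]^r_x·[Si]^r_si/[H⁺]^r_H)/K_sp
with the generic cation [X] = 1, r_x = 1, and K_sp built from the tuned
reference concentrations [Si]₀ = 0.123 mM and [H⁺]₀ = 1.9×10⁻⁵ mM. The
clay law draws [Si] and [H⁺] from the deep box (sediment interface) by
default — the physically coherent choice, and the one consistent with
[H⁺]₀ corresponding to pH ≈ 7.7, a deep-water value; a configuration flag
switches to the surface box. Abiotic silica precipitates above a threshold
∂ (0.6–0.9 mol m⁻³) as (β + α)·([Si]_ssw/∂ − 1)^1.1 from the surface box.

Clay formation consumes Alk:Si equivalents of alkalinity per mole of Si
with DIC unchanged — converting bicarbonate back to CO₂, the
carbon-recycling mechanism. Published modern Alk:Si estimates for the globally integrated clay
assemblage span roughly 0.3–0.5 (with a corresponding spread in the
implied modern F_rw); we pin 0.3 as the modern default because, with our
weathering stoichiometry, the 0.3/4.7 pair closes the preindustrial
budget almost exactly.

### Stoichiometric bookkeeping

Per mole of Si weathered from silicates: 2 mol CO₂ consumed from the
atmosphere, 2 mol DIC + 2 mol TA delivered to the surface ocean
(Urey/Ebelmen; both coefficients configurable). Carbonate weathering
consumes 1 atmospheric CO₂ and delivers 2 DIC + 2 TA per mole of rock
carbon; carbonate burial removes 1 DIC + 2 TA. With this bookkeeping the
unforced steady state satisfies F_silw = F_vc + Alk:Si·F_rw/2, so steady
pCO₂ equals pCO₂ᶜ exactly when clay alkalinity consumption is zero and
exceeds it otherwise — with the modern calibration
(pCO₂ᶜ = 140 ppm, n_si = 0.2, Alk:Si = 0.3, F_rw ≈ 4.7) landing at
≈ 280 ppm.

Carbonate burial is biogenic export (10 Tmol yr⁻¹, scaled by the
extinction phase factor) plus an inorganic term 0.5·(Ω_calcite − 1)^1.7
Tmol yr⁻¹, so suppressing biology lets TA accumulate, drives carbonate
supersaturation, and hands burial to abiotic precipitation — reproducing
the supersaturation textures of the post-extinction record. The exponent
and scale are pinned in configuration; the scale was chosen so the modern
surface Ω_calcite sits near 5.

The organic subcycle has equal constant burial and weathering
(10 Tmol yr⁻¹, δ¹³C of buried organics offset by ε_org = −25‰) plus an
export/remineralization loop (640 Tmol C yr⁻¹ from the surface, the excess
over burial remineralized in the deep box). The loop is the biological
pump: it maintains a realistic deep-minus-surface DIC gradient and hence a
deep pH near 7.5, which is what lets the printed clay K_sp constants
reproduce the modern clay flux. Its magnitude is a calibration choice of
this implementation; no published value is adopted. Volcanic carbon carries δ¹³C = −5‰, carbonate rock +2‰,
organic weathering −22‰; the released pulse defaults to −15‰ (coal +
mantle mixture, configurable). A +0.5‰ reporting offset for
carbonate-record comparison is kept as metadata only, never a process.

### Extinction scenario

At onset (5 Myr of model time) a boxcar pulse releases 30,000–55,000 Pg C
over 0.8–2.4×10⁵ yr on top of the background degassing. Biological
deposition follows the three-phase factor: linear initiation ramp (10⁵ yr)
from background to full extinction, full-extinction interval (2–7 Myr)
with k_bSi and biogenic carbonate export at their extinction values
(default zero), and a linear recovery (1–6 Myr). The extinction-interval
clay-law parameters (o, r_si, r_H, Alk:Si) interpolate linearly with the
same phase factor. In the fixed-recycling experiment (Simulation 1 style)
F_rw and its alkalinity consumption are both frozen at the spin-up value;
in the dynamic experiment (Simulation 2 style) the saturation law is
evaluated every step.

The clay-law offset o is treated as a property of the clay assemblage
shared by the background and extinction interval of a given draw (sampled
1–7 for Permian ensembles, 1 modern); r_si is 1 before the extinction and
sampled 1–6 during it, r_H 1–2 before and 1–6 during, Alk:Si 1–2 before
and 0.17–6 during.

## Numerics

Spin-up solves the algebraic steady state with a damped Newton/hybr root
solve on log-transformed tracers from a small family of initial guesses,
then verifies the drift criterion (max relative tracer change < 10⁻⁶ per
10⁴ yr); isotope ratios are solved from the linear 3×3 steady balance. If
every root attempt fails, the model is integrated in 2 Myr chunks (capped
at 20 Myr) with root polishing after each chunk. Pre-extinction spin-ups
whose equilibrium pCO₂ falls outside 300–1000 ppm are rejected and the
parameter draw is repeated (the redraw stream is seeded per member index,
so ensembles are reproducible and worker-count independent). Rejected
draws never enter summaries.

Scenario runs use LSODA with rtol 10⁻⁸ and scaled absolute tolerances,
integrating piecewise between the forcing discontinuities with a 1 kyr
step cap through the release pulse and initiation ramp and 10 kyr through
the recovery ramp. Before onset the forcing is constant and the state is
the verified steady state, so pre-onset output repeats the spin-up state
rather than re-integrating it. Output is decimated to ≥ 500 samples with
extra density around the onset transient. Runs extend to at least 15 Myr.

Clamped laws — (Ω − o), (1 − [Si]/ς), ([Si]/∂ − 1) — are continuous at
their thresholds; negative arguments give zero flux. Isotope ratios read
from the state are clipped to |δ| < 200‰ so a transient solver excursion
cannot destabilize the tendencies.

## Calibration

Free constants not printed in the source — mixing rate, organic export,
and k_bSi within its published range — were set once so the modern
steady state reproduces the modern silica budget:
V_mix = 1.9×10¹⁵ m³ yr⁻¹ (~60 Sv), F_org_export = 640 Tmol C yr⁻¹,
k_bSi = 3.2×10¹⁴. The resulting state has pCO₂ = 280 ppm, clay uptake
F_rw = 4.96 Tmol Si yr⁻¹ (published modern estimate 4.7 ± 2.3), biogenic
silica sediment rain 89.3 Tmol Si yr⁻¹ (90.2 ± 19.1), surface pH 8.1 and
deep pH 7.5. The default Permian background (o = 3.5, Alk:Si = 1.5,
pCO₂ᶜ = 300 ppm, k_bSi = 10¹³, n_si = 0.3) equilibrates at 448 ppm with
a small pre-extinction clay flux; Monte Carlo draws explore the full
printed ranges, with the 300–1000 ppm window doing the selection.

## Problem sizes

Desk-scale defaults keep a single scenario run near one second and the
shipped analyses tractable on one CPU: ensembles of 100–150 members by
default (the machinery scales to the 10⁴-member ensembles such analyses
are usually run at), mixing-model sampling at n = 500,000, and a 36-site
synthetic chert compilation. All
sampling is reproducible under a single integer seed.

## The synthetic closed loop — and its limits

The sea-surface-temperature proxy compilation that motivates the
filtering target is not redistributed here; this package ships a synthetic
piecewise-linear stand-in (+12 °C over 1.5×10⁵ yr, 5 Myr plateau, 2 Myr
decline — inside the qualitative description of the record) and treats
any user-supplied (time, anomaly) CSV identically. Mineral tables and
chert records are likewise generated with the observed qualitative
structure (pre/post step in the clay:quartz ratio; an Early Triassic
chert gap with latitude-dependent recovery).

Consequently the filtered-ensemble statistics here are *property checks*,
not reproductions: they demonstrate that dynamic clay formation sustains a
≥ 4 Myr temperature plateau that fixed recycling cannot under identical
forcing, that runs passing the synthetic filter raise the carbon residence
time severalfold (bracketing the reported 2.2–4.4×), and that filtering a
synthetic ensemble against the curve of a known configuration recovers
envelopes bracketing the generating extinction-interval Alk:Si and clay
fraction. They do not show that the real proxy record selects the same
parameter values, and the generators do not emulate proxy-specific
calibration error, age-model uncertainty, or spatial heterogeneity of
real sections.

## Known limitations

- Two boxes cannot represent basin-to-basin gradients, coastal clay
  factories, or sediment-column diagenesis; the clay law sees one deep
  [Si] and one deep pH.
- The organic subcycle is held constant through the extinction; a
  productivity collapse would alter both the deep pH lever and the δ¹³C
  trajectory.
- Weathering depends only on pCO₂ (the canonical power law), not
  explicitly on temperature or runoff.
- The inorganic carbonate precipitation law and its exponent are a closure
  choice; they control how fast burial recovers when biology is suppressed.
- Equilibrium constants are evaluated at modern salinity; Permian seawater
  major-ion chemistry is only adjustable through the calcium setting.
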