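# Methods

## The carbon-budget model

The model tracks the carbon mass CM (g C) of a single *Pelagia noctiluca*
individual in zero dimensions, forced by temperature T (°C) and ambient prey
carbon concentration F (gC·L⁻¹). The daily budget is

    dG = A − (R_C + Ex + Re)        (net growth)
    Eg = I − A                      (egestion)

with

    P   = p_max · CM^b_p · t₁₀^T / (F + k_p)      predation scaling
    I   = P · F                                    ingestion
    A   = I · (1 − a_max · F / (F + k_a))          assimilation
    R   = R_o · M^b_r · t₁₀^T                      respiration (µmolO₂·d⁻¹)
    R_C = R · β · α                                … in carbon units
    Ex  = R_C · c_e                                excretion
    Re  = (a_re · M^b_re) · W_e · c_re · spn       reproduction (gated)

Temperature acts through t₁₀ = 1.066, the tenth root of Q10, shared by
predation and respiration (per-process overrides are available).
Reproduction is active only at and above the 4 cm maturity bell diameter and
is continuous (a rate `spn` per day) rather than pulsed. p_max is coupled to
the predation half-saturation constant through the food-saturation reference
F_sat = 1.2·10⁻⁴ gC·L⁻¹: p_max = 0.1399·(1 + k_p/F_sat); whenever k_p is
drawn or replaced, p_max is recomputed.

Morphometry links carbon mass, wet mass (WM, g) and bell diameter (BD, cm):
WM = 0.075·BD^2.993 and CM = 0.26·BD^3.017 (mg), so CM/WM ≈ 0.36% across the
adult size range; the package stores carbon in grams throughout.

As written, the assimilated *fraction* decreases with increasing food
(1 − a_max·F/(F+k_a)), so at a_max = 1 assimilation vanishes at food
saturation. This is implemented literally; it is a structural feature of the
budget, visible in calibration as a_max drifting to extreme values, and is
not reinterpreted here.

### Mass bases

Two of the allometries are published with ambiguous mass conventions, so the
basis is an explicit configuration field:

* **Respiration** (`respiration_mass_basis`, default `'wm'`): R_o = 2.80
  µmolO₂·d⁻¹ is defined for a 1 g *wet mass* individual at 0 °C, although
  the rate equation is written on CM. With CM in grams a 4 cm adult
  (CM ≈ 0.017 g) would respire ~0.01% of its body carbon per day and never
  shrink; the wet-mass basis gives the observed few-percent-per-day
  starvation losses. The `'cm'` option preserves the literal equation.
* **Reproduction** (`reproduction_mass_basis`, default `'wm'`): the egg
  power law a_re·M^4.66 yields, on a wet-mass-in-grams basis, ~10²–10³ eggs
  per spawn for 4–5 cm adults — the "hundreds of eggs" scale — and a
  reproduction share of starved carbon loss of ~40–75% around the maturity
  size. On a carbon-mass-in-mg basis the same law yields ~10⁵ eggs and a
  reproductive flux more than twenty times the body carbon per day (the
  organism would not survive one day), and on carbon-mass-in-grams it
  yields effectively zero eggs (growth would never saturate). Both
  alternatives remain available (`'cm_mg'`, `'cm_g'`) but the wet-mass
  basis is the only one compatible with all three qualitative behaviors the
  model must reproduce: exponential starvation degrowth, sigmoid growth
  saturating shortly after maturity, and a bounded annual size cycle.

### Integration and numerical choices

Forward Euler at the forcing resolution (daily by default; all rates are
daily). `ForcingSeries.refine(n)` interpolates forcing for convergence
checks; the test suite verifies first-order convergence by Richardson
comparison. Diel vertical migration is represented by evaluating every rate
at the surface and at the 13 °C deep temperature and averaging with equal
12 h weights. A step that would drive carbon mass non-positive terminates
the trajectory with an explicit `exhausted` status (no silent clamping);
downstream, a truncated trajectory counts as outside the observation tunnel
from the truncation time onward, with a one-half-width distance penalty per
missing observation.

`simulate_ensemble` integrates many parameter draws simultaneously
(vectorized over draws); it is tested element-for-element against the scalar
path and against an independent re-implementation of the budget equations at
relative tolerance 10⁻¹².

## The statistical model checking engine

Each candidate is a vector of central values on the Cartesian product of
per-parameter arithmetic grids (`SearchVector`, inclusive endpoints,
index-generated to avoid floating-point drift; the published brackets
multiply out to 4,191,264 candidates). A candidate is made probabilistic by
a per-parameter *pseudo standard deviation*: each simulation draws every
searched parameter uniformly from [center − std, center + std], truncated at
0 from below (and at 1 from above for a_max), and recomputes p_max from the
drawn k_p.

A draw *matches* when its trajectory stays inside the observation tunnel of
**every** scenario at **all** observation times (linear interpolation in
time between model steps). The match probability Θ is estimated as the pass
fraction of up to n = 500 simulations (ε = 5% precision, δ = 1% error rate
in the study configuration; the Chernoff–Hoeffding bound for that (ε, δ)
actually requires n = ⌈ln(2/δ)/(2ε²)⌉ = 1060, which `chernoff_n` computes —
the engine's own precision test runs at that bound-implied size). A Wald
SPRT of H₀: p ≥ γ+ε against H₁: p ≤ γ−ε with both error rates δ prunes
candidates one-sidedly: it only ever rejects (evidence the candidate cannot
reach the γ = 70% acceptance threshold), never accepts early. ε doubles as
the SPRT indifference half-width — a single coherent precision budget.

Per-candidate random streams are seeded from (master seed, grid index), so
results are bit-identical regardless of evaluation order or batching; the
engine batches active candidates' chunks into single vectorized ensemble
calls for speed.

**Score and Dist.** Per scenario, Score is the *fraction* of a candidate's
simulations outside the tunnel (so 1 − Θ when every simulation ran and only
one scenario is active) and Dist the mean over observation times of the
excursion beyond the nearest bound, normalized by the local tunnel
half-width (degenerate zero-width bands fall back to absolute excursion).
The combined ranking error is Σ_scenarios w·(Score + Dist) with equal
weights by default; both terms are per-point quantities, so doubling a
scenario's sampling density does not change its leverage.

## Synthetic data

No observation dataset is redistributable, so the package generates inputs
with the statistical structure the analysis assumes:

* **Climatology**: 365 daily values; SST a cosine annual cycle spanning
  13–22 °C peaking in late August; zooplankton at a 10⁻⁶ gC·L⁻¹
  winter/summer baseline with a Gaussian spring bloom (σ = 30 d, day 105)
  peaking at 5.5·10⁻⁶ gC·L⁻¹; deep temperature constant at 13 °C.
* **Observations**: the ground-truth trajectory is simulated, sampled every
  2 days over 30 days (laboratory) or weekly over a year (in situ), and
  perturbed by multiplicative Gaussian noise (10% of signal, 5 replicates);
  tunnels are replicate mean ± k_std·std. Noise is multiplicative because
  size-measurement error scales with organism size.
* **Surrogate initial sizes** (the source experiments never report them):
  4.5 cm for degrowth, 1.0 cm for growth, 3.0 cm for the in-situ cohort.
  The in-situ tunnels follow a single cohort through the year.

What the generator does **not** emulate: multiple overlapping cohorts (and
their April contamination of adult size observations), inter-annual
variability, irregular sampling gaps, or any correlation structure in the
measurement error. Passing the recovery test therefore demonstrates that the
engine identifies generating parameters under the model's own dynamics and
honest measurement noise — not that the model is correct for the real
populations.

### Choice of the tunnel multiplier for recovery

The recovery experiment uses k_std = 5 (`SyntheticSpec` itself defaults to
k_std = 1 for general use). The match criterion is a *joint* band condition
over ~85 observation times, and with only 5 replicates the sample std is
occasionally far below the true σ (it is σ·χ₄/2 distributed), so a
mean ± k·s band needs a tolerance-interval multiplier rather than a normal
one: covering the true value pointwise at the 99.9% level requires
k = t₄(0.9995)/√5 ≈ 3.9 before accounting for the spread that the
pseudo-std parameter perturbation itself induces in the simulated
trajectories. Five sample standard deviations is the smallest integer
multiplier with headroom for both effects.

### Recovery experiment conditions

Reduced grid of 3 values per searched parameter at the published grid
resolutions, centered on the truth (floored at the non-negativity bound for
c_e), over the six unknown ecophysiological parameters — 729 candidates —
with F_lab pinned at its true central value but still perturbed by its
pseudo-std. 100 Monte Carlo simulations per candidate with SPRT pruning at
γ = 0.7, ε = 0.05, δ = 0.01. Success means the generating vector is
retained (Match > 0.7) with combined error minimal or within one
tunnel-normalized unit of the minimum. These problem sizes keep a 20-seed
replication of the full experiment around a minute on one core.

## POC export

A literal sequestration product Eg·w·k is dimensionally inconsistent with a
carbon flux, so the package implements the attenuation such a shorthand
stands for: a mucus particle sinking at w and remineralizing at first-order
rate k loses 1 − exp(−k·z/w) of its carbon by depth z (a linear variant
k·z/w is provided; both give ≈0.9%, i.e. 1% to the nearest percent, at
w = 751 m·d⁻¹, k = 0.034 d⁻¹, z = 200 m). Areal export is
Eg·abundance·(1 − loss)·1000 mgC·m⁻²·d⁻¹, evaluated per abundance quantile
(median 0.018, quartiles 0.003/0.1 ind·m⁻²) and expressed against the
DYFAMED reference fluxes (14.01, 13.55, 1.53 mgC·m⁻²·d⁻¹ in February, April
and July) where available. The default horizon is 200 m and the default
sinking speed the median 751 m·d⁻¹.

## Known limitations

* No mortality, jelly falls, advection or population dynamics — the budget
  is strictly per-individual.
* The starved loss partitioning depends on the (unreported) initial size of
  the degrowth animals; at the 4.5 cm surrogate the model attributes ~27%
  of day-0 losses to respiration and ~73% to reproduction, shifting toward
  respiration as the animal shrinks past maturity.
* The fixed literature regressions behind p_max, R_o and a_re are taken as
  constants and never refitted.
* Tunnels over a single output variable are the only property class; there
  is no general temporal-logic layer, and exact probability computation is
  out of scope by design.
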