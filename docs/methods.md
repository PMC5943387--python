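# Methods

## Scope and units

The package models aerobic (and denitrifying) toluene degradation in two
bench systems: well-mixed closed bottles, and 1.6 cm flow-through
sediment columns fed continuously through a Danckwerts-type inlet.
Internally every module uses one unit convention: length m, time day,
aqueous concentrations µM (µmol L⁻¹ of pore water), mobile cells
cells mL⁻¹ of pore water, attached cells cells mL⁻¹ of bulk sediment.
I/O-facing code accepts bench units (cm, mL h⁻¹, mm, s) and converts at
the boundary. The longitudinal dispersion coefficient is stored in SI
(1.95×10⁻⁸ m² s⁻¹) and converted once to 1.685×10⁻³ m² day⁻¹ to avoid
repeated-conversion drift.

## Batch models

The standard model is Monod growth with yield coupling (electron
acceptor in excess, no decay term), integrated by an adaptive explicit
Runge–Kutta scheme (scipy RK45, rtol 1e-8). Conservation
X = X₀ + Y(c₀ − c) is exact in the equations and is asserted per time
point in the tests.

The two-step variant routes toluene through a generic metabolite pool:
transformation without growth at specific rate r_tol_max, growth on the
metabolite at r_met_max. The pool is deliberately named `metabolite`
everywhere — its chemical identity is not resolved by the data the model
is built for. Its conserved quantity is c_tol + c_met + (X − X₀)/Y. The
half-saturation K_met of the second step is treated as a free nuisance
parameter: the printed record the parameter file transcribes reports the
two maximum rates only as Y-scaled values (24.06 d⁻¹ and 4.19 d⁻¹) and
never K_met itself.

## Column model

Four fields on a cell-centred finite-volume grid (inlet at x = 0, cells
indexed inlet→outlet): toluene, oxygen, mobile cells, attached cells.
Attached growth is dual-Monod; mobile growth carries a configuration
flag and is **off** by default — at a 12.7 min water residence time the
mobile population cannot grow appreciably, and enabling it does not
change the results. Setting K_ox = 0 with f_ox = 0 disables the acceptor
factor entirely (single-Monod mode), which is how the denitrifier column
is run when no acceptor kinetics are constrained; an explicit nitrate
mode is obtained by supplying the acceptor half-saturation and
stoichiometry as K_ox/f_ox values for the nitrate feed.

**Porosity bookkeeping.** Attached cells are counted per bulk-sediment
volume while aqueous concentrations are per pore-water volume, so the
substrate and oxygen sinks of attached growth carry a 1/n factor:
(1/(nY))·r_att. Equations that print the sink as (1/Y)·r_att while
applying n-factors to the cell-exchange terms do not close their mass
balance; the implemented form does, and the tests assert closure of both
the toluene and the cell balance to solver tolerance at every output
time.

**Boundaries and initial state.** Flux (Danckwerts) inlet — the
advective flux carries the feed concentration, no diffusive flux crosses
the inlet face — and advective outflow with zero diffusive gradient.
The inoculum (default 10⁵ cells) starts uniformly distributed and fully
attached, X_mob(0) = 0, aqueous fields 0: the bench protocol lets the
inoculum stand in the column before flow starts, and attachment is fast
relative to the experiment.

**Inlet oxygen.** The feed oxygen concentration is a config value; the
source experiments report only consumption differences. Where the
reported ΔO₂ is consistent with the fitted stoichiometry (low-flow and
high-flow runs) the bundled configs use it directly; where it is not
(standard-flow run: ΔO₂ = 203 µM but f_ox·ΔTol = 238 µM) the config
reconstructs the feed from the run's own steady stoichiometry
(f_ox·ΔTol ≈ 240 µM, oxygen fully consumed in-column). This is a
reconstruction from the experiment's internal arithmetic, not a tuning
knob.

**Numerics.** Implicit Euler in time with an analytic-Jacobian
Newton–Raphson solve of the fully coupled system each step; convergence
is a relative update norm < 10⁻⁸ (per-field absolute floors: 10⁻³ µM,
1 cell mL⁻¹), at most 20 iterations. Steps are adaptive: halve on a
rejected step, grow 1.5× after convergence in ≤ 5 iterations, capped at
dt_max = 600 s; the grow/halve heuristic is this package's choice — the
adaptivity criterion was not specified in the source. Advection is
first-order upwind; at the default dx = 0.5 mm (32 cells) the numerical
dispersion v·dx/2 is ~25% of D at the standard flow, which leaves steady
states essentially unchanged (halving dx moves the steady outlet by
≪1%) but smears fast transients — the transport-oracle tests therefore
run refined grids/steps when comparing against closed-form transients.
The linear systems are small and dense (4N ≈ 128 unknowns) and solved
directly.

**Oracles.** Two closed forms check the solver: the semi-infinite
advection–dispersion breakthrough (conservative tracer, Péclet ≈ 17,
where inlet-condition mismatch and residual numerical dispersion bound
agreement at the few-percent level on a refined grid) and the exact
Danckwerts steady profile for first-order decay (frozen uniform biomass,
c ≪ K_tol so Monod is linear with λ = 10³·µ_max·X_att/(n·Y·K_tol)),
which the solver matches to <1% at dx = 62.5 µm.

**Logistic variant.** An alternative formulation drops the explicit
mobile-cell field and throttles only the growth term by
(1 − X_att/X_att_max) while substrate consumption keeps the unthrottled
rate. At steady state it reproduces the full model's toluene profile to
<0.1% on the standard-flow configuration — capacity-limited export and
logistic growth-limitation are equivalent once the attached pool is
full.

**Observables.** The three oxygen "probe" outputs and the attached-cell
observables are averages over the FV cells in each third of the column
(bottom/middle/top), mirroring sectioned sediment analysis and the three
optode spots.

## Calibration

Both fitters minimize a weighted least-squares objective: concentrations
on the linear scale, cell counts in log₁₀ (counts span four orders of
magnitude), each series divided by its noise SD — estimated from
replicate scatter when replicates are present, else the generator
defaults. Parameters are optimized as natural logs (positivity for
free), bounded ±4 decades around the initial guess, from multiple
Latin-hypercube starts (ties: lowest objective, then lexicographically
smallest vector). Standard errors are Gauss–Newton,
cov = s²(JᵀJ)⁻¹, delta-propagated to the linear scale; a Jacobian
condition number above 10⁸ flags the free set as non-identifiable.
Counts below the flow-cytometry detection floor (default 10³ mL⁻¹) are
treated as left-censored: model and observation are clamped at the floor
so a prediction below an at-floor observation costs nothing. Batch
observation sets may contain several bottles (different starting
concentrations) fitted jointly with shared parameters — high-substrate
bottles pin µ_max and Y, near-K bottles pin K_tol; single bottles at one
concentration leave K_tol only ~15%-identifiable at realistic noise.

The column fit frees (µ_max, f_ox, k_att) at most. k_att deserves a
note: on the dissolved-phase observations (toluene, oxygen) the
objective is flat to <5% across k_att ∈ [25, 100] d⁻¹ — removal is
insensitive to the attachment coefficient. The outlet-cell series during
the colonization transient, however, does inform k_att (attachment
attenuates the export of daughter cells through the uncolonized part of
the bed), so on model-generated data the full objective is not flat; the
insensitivity statement is about the dissolved phase and about real data
whose misfit floor swamps the effect.

## Synthetic data

The generator runs the forward models under the study design (sample
times; sacrifice times at which whole virtual columns are consumed for
sectioned attached-cell counts — no repeated measures) and applies the
noise model: additive Gaussian SD 3 µM on concentrations (truncated at
zero), mean-corrected multiplicative lognormal noise with CV 0.2 on all
counts, a 10³ mL⁻¹ reporting floor, triplicates. The magnitudes are this
package's stipulation — the emulated protocols report triplicate means
± SD but no error model — and are config-exposed. A community variant
scales the initially attached degrader pool by an active fraction and
adds the inactive background as a constant offset to reported attached
counts.

What the generator does *not* emulate: instrument drift, calibration
error, flow-rate fluctuations, spatial heterogeneity of packing, sorption,
or any structural model error. Passing recovery tests therefore
demonstrate that the estimation machinery is correct and that the designs
carry enough information at realistic noise — not that the model is an
adequate description of any particular real column.

## Problem sizes used in the tests

Chosen once as realistic bench-scale designs: batch recovery uses two
bottles (150 and 30 µM) × 12 time points × triplicates × 20 seeds with
the spiked initial states treated as known; column recovery uses the
standard-flow configuration over 96 h (12 sample times, 2 sacrifice
times) × 10 seeds with single-start fits from a ~40%-perturbed guess;
the headline forward runs use the full 192 h at dx = 0.5 mm.

## Known limitations

- 1-D, saturated, constant flow; no transverse dispersion, sorption,
  biomass decay/maintenance, substrate inhibition, or permeability
  feedback from pore clogging.
- The carrying capacity X_att_max is prescribed, not mechanistic.
- First-order upwind advection smears sharp fronts at the default grid;
  refine dx/dt_max for transient-accuracy work.
- Reported residence times in the emulated study ("6.5–38.5 min" for
  1–6.6 mL h⁻¹) are mildly inconsistent with its own geometry, which
  gives 6.2–40.6 min; the package follows the geometry arithmetic.
- The bundled parameter tables carry `uncertain` flags where the printed
  sources conflict (e.g. two yields differing 10× for the denitrifier
  column; two µ_max readings for the aerobe batch fit) rather than
  silently choosing a reading.
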