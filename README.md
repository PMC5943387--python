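# monodcol

Biodegradation kinetics of a model groundwater contaminant (toluene) in
two laboratory systems: closed batch bottles and 1-D flow-through mini
sediment columns. The package provides the forward models, their
calibration against tidy observation tables, the stoichiometric yield
accounting that links oxygen consumption to biomass carbon, and a seeded
synthetic-data generator that emulates the bench sampling protocols — so
the whole estimation pipeline is testable end to end without lab data.

It is aimed at people modelling contaminant plumes and column
experiments: microbial ecologists and reactive-transport modellers who
need a transparent, tested reference implementation of the standard
batch/column model stack rather than a general-purpose simulator.

## Models

**Batch growth.** Standard Monod kinetics,

```
dX/dt = µ_max · c/(c + K_tol) · X        dc/dt = −(1/Y) · dX/dt
```

with an exact first integral X = X₀ + Y(c₀ − c); and a two-step variant in
which toluene is first transformed (without growth) to a metabolite
intermediate that the cells then grow on — needed when cell numbers keep
rising after the parent compound is gone. In the fast-second-step limit
the two-step model collapses onto standard Monod with µ_max = Y·r_tol_max.

**Column reactive transport.** Four coupled fields on a cell-centred
finite-volume grid — aqueous toluene and oxygen, mobile (pore-water) cells
and sediment-attached cells:

```
∂c_tol/∂t = −v ∂c_tol/∂x + D ∂²c_tol/∂x² − (1/(nY)) r_att
∂c_ox/∂t  = −v ∂c_ox/∂x  + D ∂²c_ox/∂x²  − (f_ox/(nY)) r_att
∂X_att/∂t = r_att + n·r_attach − r_daughter
∂X_mob/∂t = −v ∂X_mob/∂x + D ∂²X_mob/∂x² − r_attach + (1/n) r_daughter
```

Growth of attached cells is dual-Monod in the electron donor and
acceptor, r_att = µ_max·M(c_tol)·M(c_ox)·X_att. The attached population
saturates at a carrying capacity X_att_max: new-grown cells are released
to the pore water by the growth-proportional daughter rate
r_daughter = r_att·X_att/X_att_max, and attachment of mobile cells,
r_attach = k_att·X_mob·(1 − X_att/X_att_max), shuts off as capacity is
approached. Time integration is implicit Euler with adaptive steps and a
Newton solve of the coupled nonlinear system; advection is upwind, the
inlet is a flux (Danckwerts) boundary.

**Yield accounting.** Two independent routes to the carbon assimilation
efficiency: 1 − f_ox/9 from the oxygen/toluene consumption ratio (9 is
complete mineralization of C7H8), and cell counts × 130 fg C per cell
(0.5 µm³ prolate-spheroid biovolume at 260 fg µm⁻³) per µmol toluene
carbon.

## Worked example

Simulate the standard-flow column experiment (65 µM toluene at
3.2 mL h⁻¹, i.e. 1.8 m day⁻¹ pore velocity) from its bundled config and
summarize the quasi-steady state:

```python
import monodcol as mc

cfg = mc.bundled_config("exp_B")
record = mc.simulate_column(cfg)          # 192 h, dx = 0.5 mm
summary = mc.steady_state_summary(record)
print(summary)
print(mc.cumulative_toluene_degraded(record))
```

prints (rounded):

```
steady: True
dTol: 60.0            # µM removed between inlet and outlet
dOx: 240.0            # µM oxygen consumed
outlet_X_mob: 2153353 # suspended cells/mL exported at steady state
f_ox_empirical: 4.0   # ΔO₂/ΔTol
removal_pct: 92.3     # toluene removal efficiency
cumulative_umol_192h: 31.4
```

92% removal at this flow, a few 10⁶ suspended cells mL⁻¹ flushed out
while ≥98% of the biomass stays attached, and an f_ox of 4.0 —
equivalently a carbon assimilation efficiency of 1 − 4.0/9 ≈ 0.56.
The outlet cell number is the flux balance Y·ΔTol: once the sediment
is at carrying capacity, every newly grown cell leaves with the water.

The same pipeline is scriptable from the shell:

```
monodcol simulate-column --config src/monodcol/data/exp_B.yaml --out run/
monodcol summarize run/
monodcol generate-data --config src/monodcol/data/exp_B.yaml --seed 7 --out synth/
```

## Layout

- `monodcol.geometry` — domain types, units, column/flow arithmetic
- `monodcol.batch` — batch models and their calibration
- `monodcol.column` — the finite-volume reactive-transport model,
  steady-state summaries, calibration
- `monodcol.stoichiometry` — f_ox, biovolume, cell carbon, yields
- `monodcol.synth` — seeded synthetic observation sets
- `monodcol.io` / `monodcol.cli` — configs, tidy CSV tables, bundled
  experiment fixtures (`exp_A` … `exp_G`), command-line interface

See `docs/methods.md` for the modelling assumptions, unit conventions,
numerical choices and known limitations.
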