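# biosorb

Modelling toolkit for batch heavy-metal biosorption studies, built around
the analysis chain of Cu²⁺ removal by lignocellulosic sorbents (raw olive
waste powder, its sodium-alginate composite beads, and pure alginate):

* **Equilibrium** — the statistical-physics single-layer isotherm coupled
  to a real-gas description of the dissolved solute (SLMRG), fitted by
  bounded multi-start least squares.
* **Kinetics** — pseudo-first-order, pseudo-second-order and Weber–Morris
  intraparticle-diffusion models, via both the classical linearizations and
  nonlinear fits, including multi-regime diffusion segmentation.
* **Thermodynamics** — ΔG° = −RT ln K and the van't Hoff regression for
  ΔH°, ΔS°, with physisorption/chemisorption classification, plus
  point-of-zero-charge determination from pH-drift titrations.
* **Reactivity descriptors** — conceptual-DFT global descriptors from
  frontier-orbital energies, COSMO-RS σ-profile region analysis and QTAIM
  bond-critical-point classification (post-processing only; no electronic
  structure is computed here).
* **Synthetic data** — seeded generators for every input the pipeline
  consumes, so the whole chain is testable without laboratory data.

It is aimed at environmental physical chemists who want the statistical
analysis of a biosorption paper as reusable, tested code.

## The model at the core

Each of the `Nm` receptor sites (mg/g) binds `n` solute molecules; in the
grand-canonical ensemble the equilibrium capacity is

```
qe(Ce) = n·Nm / (1 + (w / f(Ce))^n)
f(Ce)  = Ce/(1 − b·Ce) · exp(b·Ce/(1 − b·Ce)) · exp(−2aβCe),   β = 1/(kB·T)
```

where `f` is the van der Waals fugacity of the solute (co-volume `b` in
L/mg, cohesion pressure `a` tabulated in 10⁻²³ J·L/mg) and the energetic
parameter `w` (mg/L) decomposes as `w = Cs·exp(−Ea/RT)`. At `a = b = 0`
this is the Hill isotherm, and Langmuir for `n = 1`; the saturation
capacity is `Qsat = n·Nm`. See `docs/methods.md` for assumptions,
parameter identifiability and the published-equation reconstruction notes.

## Worked example

```python
import biosorb as bs

# a synthetic composite-bead isotherm at 293 K with 2% multiplicative noise
params = bs.SLMRGParams(n=2.86, nm=44.712, a=8.75, b=0.0071, w=10.788)
spec = bs.GeneratorSpec(seed=7, noise_model="multiplicative-gaussian", noise_sd=0.02)
data = bs.gen_isotherm(params, 293.0, spec, adsorbent_id="OWPSA")

res = bs.SLMRG(data).fit(bs.FitOptions(n_starts=32, seed=7))
print(res.summary())
```

```
SLMRG isotherm (OWPSA, 293 K) fit
---------------------------------
         n : 3.05455
        nm : 42.1597
         a : 9.39809
         b : 0.00742159
         w : 10.3015
       R^2 : 0.999892
      RMSE : 0.470597
     n_obs : 12
 converged : True
    starts : 32
      Qsat : 128.779 mg/g
```

The fit recovers the generating parameters to within a few percent at 2%
noise; `Qsat ≈ 128.8 mg/g` against the true `n·Nm = 127.9 mg/g`. The
thermodynamic side works the same way:

```python
series = bs.ThermoSeries([293.0, 303.0, 313.0], [1.6829, 2.0825, 2.5422], "OWPSA")
print(bs.VantHoff(series).fit().summary())
```

```
van't Hoff analysis (OWPSA)
---------------------------
   T [K]       Kads   dG0 [kJ/mol]
   293.0     1.6829         -1.268
   303.0     2.0825         -1.848
   313.0     2.5422         -2.428
dH0 = 15.7263 kJ/mol
dS0 = 0.0580 kJ/(mol K)
R^2 (van't Hoff) = 1.000000
regime: physisorption
```

Negative ΔG° at every temperature means spontaneous adsorption; the
positive ΔH° below the 40 kJ/mol chemisorption threshold indicates an
endothermic, physisorption-dominated process.

The same operations are available from the shell — `biosorb simulate`,
`biosorb fit-isotherm`, `biosorb fit-kinetics`, `biosorb thermo`,
`biosorb pzc`, `biosorb descriptors`, and `biosorb run-study --config
study.yaml` for the whole chain on a set of files.

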