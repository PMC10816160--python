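# Methods

This note records the models implemented in `biosorb`, the assumptions and
numerical choices behind them, what the synthetic-data generators emulate,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Equilibrium: the SLMRG isotherm

The single-layer model coupled to a real gas treats adsorption as an
exchange of solute between the solution and `Nm` identical, independent
receptor sites per gram of sorbent, each site binding `n` molecules
(fractional `n < 1` means one molecule bridges `1/n` sites). In the
grand-canonical ensemble the occupation probability gives

    qe(Ce) = n·Nm / (1 + (w / f(Ce))^n),

with saturation capacity `Qsat = n·Nm`. The solution is treated as a van
der Waals fluid, so the driving quantity is not `Ce` but the fugacity-like
effective concentration

    f(Ce) = Ce/(1 − b·Ce) · exp(b·Ce/(1 − b·Ce)) · exp(−2aβCe),

with co-volume `b` (L/mg), cohesion pressure `a` and `β = 1/(kB·T)`. `f`
diverges at the packing bound `Ce = 1/b`, which is therefore a hard domain
edge (the fitter caps `b ≤ 0.9/max(Ce)`). `qe(0)` is defined as 0 by
continuous extension. At `a = b = 0` the model reduces exactly to the
Hill form `n·Nm/(1 + (w/Ce)^n)` and to Langmuir for `n = 1`; the unit
tests assert both reductions to 1e−12 relative.

**Reconstruction note.** The typeset source equation for this model is
garbled (ambiguous factor grouping, unreadable exponent sign). The form
above is the standard van der Waals fugacity — `ln f = ln(c/(1−bc)) +
bc/(1−bc) − 2aβc` — which matches the printed factor order and the model's
statistical-physics lineage. The attraction term carries a *negative*
exponent: cohesion lowers the fugacity. A consequence worth knowing: for
strong cohesion (the alginate parameter sets at 303/313 K, where `a` is
5–8× larger than for the other sorbents), `f` turns over inside the domain
and the model isotherm is no longer monotone at high `Ce`. The property
tests therefore assert the sharp invariant — `qe` increases with `f`, so
it is nondecreasing exactly where `f` is — and blanket monotonicity only
for the weak-cohesion parameter sets.

**Units of `a`.** The cohesion pressure is stored in units of 10⁻²³
J·L/mg, the convention of the published parameter table, so with
`kB = 1.380649×10⁻²³ J/K` the factor `2aβCe = 2a·Ce/(1.380649·T)` is
dimensionless and O(1) at tens of mg/L. (The symbol list of the source
gives "J·L/mol", inconsistent with the tabulated magnitudes; the table
convention is adopted.)

**Energetic parameter.** `w` decomposes as `w = Cs·exp(−Ea/(R·T))` with a
reference concentration `Cs` (plausibly the solute solubility; never given
numerically in the source, hence a required user input) and adsorption
energy `Ea = R·T·ln(Cs/w)`. A fitted `w > Cs` yields negative `Ea`; since
`Cs` is user-supplied and uncertain, this is reported with a warning, not
rejected. The per-molecule partition-function form of the same relation
is not implemented: its quantities are never available numerically.

## Fitting

`SLMRG(data).fit()` minimizes the unweighted sum of squared capacity
residuals with `scipy.optimize.least_squares` (trust-region reflective,
bounds, `x_scale="jac"`, tolerances 1e−14). Default bounds: `n ∈ [0.1,
10]` (relaxed below 1 for bridging adsorption), `Nm ∈ (0, 10⁴]` mg/g,
`a ∈ [0, 10³]`×10⁻²³ J·L/mg, `b ∈ [0, 0.9/max(Ce)]` L/mg, `w ∈ (0, 10⁴]`
mg/L. Starting points: a few data-driven heuristics (plateau-based
`Qsat`, half-saturation `w`, several `n` hypotheses) plus seeded
Latin-hypercube draws over the bounds (log-spaced in the scale parameters
`Nm`, `w`), 32 starts by default; the best local optimum wins. On
noiseless 15-point synthetic isotherms this recovers all nine published
parameter sets to machine precision; at 2% multiplicative noise the
median relative parameter error over 20 seeds stays below an envelope
(4–5% per parameter) established once by an independent brute-force
random-search + Nelder–Mead oracle, which found the same optima as the
packaged fitter.

Goodness of fit is `R² = 1 − SSE/SST` (SST about the observed mean) and
`RMSE = √(SSE/N)` with no degrees-of-freedom correction; the convention
of the published table is unstated, so exact RMSE matching is a non-goal.
A constant observed series leaves R² undefined (NaN with a warning).

## Kinetics

Forward models are the integrated forms: PFO `qt = qe(1 − e^{−k1·t})`,
PSO `qt = qe²k2t/(1 + qe·k2·t)`, Weber–Morris `qt = kid√t + c`. The
classical linearizations are implemented as estimators: `log10(qe_exp −
qt)` on `t` for PFO (requires the experimental plateau `qe_exp`, matching
standard practice; the factor is `ln 10`, not the rounded 2.303, so
noiseless round trips are exact) and `t/qt` on `t` for PSO (lossless on
exact data; a zero intercept — constant `qt` — is flagged degenerate with
`k2` unidentified). Nonlinear fits use the same multi-start least-squares
machinery and agree with the linearizations to 1e−6 on noiseless traces.

Multi-regime intraparticle diffusion (`fit_ipd_segments`) fits piecewise
OLS lines in `√t` with breakpoints found by exhaustive search over
contiguous index partitions (traces are short, so the search is cheap;
each segment needs ≥ 2 points; ties go to the earliest breakpoint). The
conventional reading of the regimes is film diffusion → intraparticle
diffusion → equilibrium plateau; the first segment's intercept is tested
against `origin_tol` (default 0.5 mg/g) to report boundary-layer control.

## Thermodynamics and surface charge

`ΔG° = −R·T·ln K` (R = 8.314 J/(mol·K), natural log, K dimensionless as
supplied — how K was derived from measurements is outside this package's
scope). The van't Hoff regression of `ln K` on `1/T` gives `ΔH° =
−R·slope` and `ΔS° = R·intercept`; with exactly two temperatures the line
is exact and R² = 1 by construction. Classification uses the conventional
40 kJ/mol threshold, strict (`ΔH° = 40` is physisorption). The point of
zero charge is the first zero crossing of ΔpH vs initial pH, linearly
interpolated between the bracketing titration points; multiple crossings
take the first, matching the single-intersection reading of typical drift
curves.

## Reactivity descriptors

From frontier-orbital energies (eV): gap `= E_LUMO − E_HOMO`, chemical
potential `μ = (E_HOMO + E_LUMO)/2`, electronegativity `χ = −μ`, hardness
`η = gap/2`, electrophilicity `ω = μ²/2η`, all from unrounded inputs.
Two maximum-charge-transfer conventions coexist in the literature and
both are implemented: the pairwise electronegativity-equalization flow
`(χ_acceptor − χ_donor)/(2(η_acceptor + η_donor))` and the single-species
saturation value `χ/η`. The single-species form is the default because it
is the one published descriptor tables for these systems actually follow;
the pairwise form gives materially different numbers (e.g. ≈ 0.89 for the
Cu²⁺/alginate pair versus 1.24 for alginate alone).

σ-profiles are partitioned at the conventional ±0.0075 e/Å² edges into
hydrogen-bond-donor (σ < −0.0075), nonpolar and acceptor (σ > +0.0075)
regions by trapezoidal integration, with boundary points interpolated
onto the grid; tails beyond ±0.03 join the adjacent polar region so the
three fractions always sum to one.

QTAIM bond critical points are classified from `∇²ρ`, `G(rc) ≥ 0`,
`V(rc) ≤ 0`: negative Laplacian → covalent; positive Laplacian with
`G/|V| < 1` (equivalently total energy density `H = G + V < 0`) →
partially covalent closed-shell interaction; otherwise weak noncovalent.
The `H` sign is the tiebreaker, consistent with common practice; the
boundary `G/|V| = 1` counts as noncovalent. Hydrogen-bond energies at
BCPs are deliberately not computed: the defining formula is not available
in the source material, and guessing one (e.g. `V/2`) would fabricate a
quantity.

## Synthetic data

Generators draw from the exact forward models with seeded NumPy
`default_rng`; everything is bit-reproducible per seed. Noise is
multiplicative Gaussian by default (constant relative error — the
defensible choice when capacities span an order of magnitude across
datasets); additive Gaussian is available. Default designs: 12 log-spaced
`Ce` points in `[1, 0.8/b]` mg/L mimicking batch isotherm series; 16
log-spaced times up to 480 min for kinetics; pH 2–12 in 0.5 steps for
titrations, with drift `ΔpH = A·tanh((pzc − pH)/w)`. The study-condition
sizes used throughout the tests — 15-point isotherm grids, 2% relative
noise, 20 seeds for the recovery study — mirror typical batch-experiment
designs. What the generators do *not* emulate: instrument error structure
(AAS), pH-dependent speciation or precipitation of the metal, sorbent
heterogeneity between replicates, or σ-profiles derived from molecular
structure. Passing round-trip tests therefore demonstrates estimator
correctness and identifiability under the stated noise model, not
robustness to real-world systematic error.

## Known limitations

* Single-solute, single-layer equilibrium only; no competitive multi-ion
  or multilayer models, no breakthrough dynamics.
* Unweighted least squares; no robust losses, no AIC/BIC model selection,
  no parameter uncertainty intervals beyond residual diagnostics.
* K(T) series are consumed as given; deriving equilibrium constants from
  isotherms involves unit conventions this package does not arbitrate.
* Published parameter tables are printed rounded; quantities recomputed
  from them can differ from the published derived values by more than the
  printed precision (the test suite documents the affected cells).
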