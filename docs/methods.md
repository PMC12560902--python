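# Methods

## Scope and data

The package operates downstream of computational fluid dynamics: it takes
drag coefficients of tagged and untagged sharks as input and derives
burden metrics from them.  It ships the simulated coefficients for a mako
shark at five fork lengths (1, 1.5, 2, 2.5 and 2.95 m) and eight swim
speeds (0.5–9.1 m/s) in three configurations — untagged, a body-pinned
archival tag, and a fin-mounted transmitter (2.95 m only) — 88 cells in
all, transcribed verbatim at their printed three-decimal precision
(`src/tagburden/data/table2_cd.csv`).  The four archival attachment sites
along the dorsal flank share one coefficient column; site-specific force
differences are qualitative (site 3/4 preferable) and not tabulated.
Geometry preparation, meshing and RANS solving are out of scope; the only
solver-facing helper is the rule-of-thumb inlet initialisation
k = ⅔(U·Ti)², ε = 0.09^¾ k^{3/2}/(0.07 L), ω = ε/k, with a default
turbulence intensity of 2% (documented as an assumption — the mesh study
value; production runs may have differed).

All quantities are SI and units are fixed by the file-format contracts;
no unit inference is attempted.

## Key parameters and defaults

| parameter | default | why |
|---|---|---|
| density ρ | 1025 kg/m³ | seawater at 20 °C, the habitat band |
| viscosity μ | 0.00109 Pa·s | same |
| frontal area A | 0.12/2.95² · L² | never published; slender-body plausible value at L = 2.95 m |
| mass model | 17 kg at 1 m, exponent 3 | published anchor, isometric default; both overridable |
| day length | 86 400 s | "daily" is otherwise undefined |
| glide fraction | 0.07 | tracked time share of unpowered gliding |
| cruise speed | 1 m/s | tracked cruising speed |
| burst speeds | 3.6, 5, 7.8, 9.1 m/s | the modelled burst scenarios; sub-adult sizes fix 3.6 m/s |
| burst fractions | 0–20% in 1% steps | stated range; the 1% step is this package's choice and defines the grid weighting of any grid mean |

Frontal area deserves emphasis: every ratio metric (percent drag
increase, percent energy increase, speed reduction) is provably
independent of A, ρ and day length — `energy_increase` computes the
dimensionless sum Σ frac·C_D(v)·v³ per table so the cancellation is exact
to the bit, not merely to rounding.  Absolute forces and energies (in N
and J) do depend on A and carry that caveat in reports.

## Interpolation

Lookup between grid knots is log-log linear in speed — the coefficients
decay approximately as a power law in Reynolds number, and a log-log
interpolant is exact at knots and monotone-preserving on monotone columns
— then linear in fork length across the five sizes.  Queries outside
[0.5, 9.1] m/s × [1, 2.95] m are clamped to the edge with a logged
warning by default; a strict mode raises instead.  No behaviour outside
the simulated sweep is claimed.

## Energetics and speed compensation

Daily energy is E = Σ_b t_b·F_D(v_b)·v_b with gliding contributing
exactly zero.  The equal-power burst-speed reduction has two variants
because the published procedure is ambiguous about whether drag is
re-evaluated at the reduced speed:

- `fixed_force` (default): drag held at its burst-speed value, reduction
  = δ/(1+δ) for a fractional drag increase δ.  Reverse-engineering the
  published ~22.5% reduction for a 27–31% drag increase shows this is the
  arithmetic actually used (a cubic-law solution would give ≈8%).
- `cd_interpolated`: solves C_D,tag(v′)·v′³ = C_D,untag(v_b)·v_b³ by
  bisection on [0.5, v_b] to 10⁻⁶ m/s; the power curve is monotone there
  for monotone tables.  Under a constant coefficient ratio this equals
  the closed form v′ = v_b(1+δ)^(−1/3), which the tests use as the
  root-finder's oracle.  When the tagged drag does not exceed the
  untagged drag at v_b (true of the archival column at high speed) the
  reduction is zero.

Neither variant is asserted to be the "true" reading; both are reported
side by side.  Weight-rule checks use tag mass in air (as such
assessments conventionally do, despite the known in-water caveat) and
count the threshold boundary as within the rule.

## Synthetic sweeps

The surrogate C_D(Re) = pressure_cd + form_factor·0.074·Re^(−1/5)·(S_w/A)
+ tag_drag_area_ratio emulates what a steady-RANS drag sweep looks like
statistically: a monotone power-law decay with Re, a near-constant
additive offset for a tag, and small cell noise (independent Gaussian on
the coefficient scale, truncated at zero, default sd 0.002 ≈ the printing
precision of the packaged tables).  Defaults (form factor 1.15, S_w/A =
25, zero pressure term) put the noiseless adult column in the 0.065–0.13
band of the simulated data.  It captures none of the physics the real
sweep contains — no separation, no transitional boundary layer, no
placement dependence, no lift/side/moment response — so tests passing on
surrogate data demonstrate pipeline correctness and estimator behaviour,
not hydrodynamic fidelity.

Fitting is ordinary least squares on the Re^(−1/5) basis.  The pressure
term and tag term are both speed-independent, so a single table
identifies only their sum: the fit returns a combined friction scale and
one constant offset (unconstrained in sign; the packaged untagged column
fits with a slightly negative offset), and a paired tagged/untagged fit
recovers the tag drag-area ratio as the difference of offsets.  A
constant column or fewer than four speed knots is rejected as degenerate.

## Numerical and reporting conventions

Budget fractions must sum to 1 within 10⁻⁹; burst speed ≥ cruise speed >
0.  Human-readable reports round C_D to 3 significant figures and
percentages to 1 decimal, matching the source tables' conventions; raw
precision CSVs are always written alongside.  The reference table's
energy column uses a reference budget bursting 5% of the day at the row's
speed; rows with speed below the 1 m/s cruise speed leave the
energy/reduction columns blank, since no valid budget bursts slower than
it cruises.  Scenario grids in the shipped pipeline cover 4 burst speeds
× 21 fractions × 2 tag configurations (168 scenarios), which runs in
well under a second; all pipeline outputs except the timestamped log are
byte-deterministic for a fixed configuration.

## Known limitations

- The packaged coefficients carry three-decimal rounding.  Consequences:
  the archival tag's cruise-speed energy increase is exactly 0% from the
  table (unrounded forces gave 0.8%); the fin-mount drag-increase band
  recomputes to ≈18.2–27.3% rather than the published 17.6–31.2%; and the
  fin-mount energy increase is not strictly monotone in burst speed —
  the 9.1 m/s coefficient ratio (0.084/0.066) falls marginally below the
  7.8 m/s ratio (0.086/0.067), so the monotone-growth claim is asserted
  only over 3.6→5→7.8 m/s.  Published absolute energies (kJ) depend on
  unprinted raw forces and frontal areas and are treated as
  order-of-magnitude context only.
- Low-speed (≤1 m/s) simulated cells converged less stably in the source
  simulations; the noise model nevertheless treats all cells identically,
  as nothing quantitative is known about the excess uncertainty.
- Rigid-body, steady-flow assumptions throughout: no undulatory
  propulsion, no dermal-denticle microstructure, no buoyancy or gravity,
  no behavioural compensation dynamics.  Lift and side-force tables are
  not packaged (never published numerically); the coefficient containers
  support them for user-supplied data only.
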