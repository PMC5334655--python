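# Methods

## The hydraulic-force model

During diastole the open mitral valve makes the left atrium and ventricle a
single hydraulic compartment, so the same blood pressure acts on both sides
of the atrioventricular (AV) plane. For apex-to-base force balance only the
largest cross-sections orthogonal to the long axis matter — the atrial
short-axis area (ASA) and the ventricular short-axis area (VSA) — however
curved the intervening anatomy is. The net longitudinal force is

    F = P_lv · VSA − P_la · ASA,

positive apex-to-base (toward the base, aiding filling). The package
computes this in SI units (Pa, m², N) and converts at the interface with
the exact definition 1 mmHg = 133.322368 Pa; areas are supplied in cm².
Assumptions inherited from the underlying physiology:

- **Equal chamber pressures** (default 10 mmHg): transmitral and
  intraventricular gradients during early rapid filling are neglected,
  justified because the force is largest during diastasis, when gradients
  have dissipated. Unequal pressures are supported by disabling the
  equal-pressure flag.
- **Two VSA definitions bracket the truth.** Blood pressure certainly acts
  on the endocardial border (`vsa_endo`); intramyocardial fluid pressures
  may extend the effective area to the epicardial border (`vsa_epi`). All
  forces are reported for both; no attempt is made to model the myocardium
  itself.
- Radial and torsional force components, aortic-wall recoil and
  restoring-force mechanics are out of scope; the driving-force comparison
  treats the peak driving force as a given per-unit-mass constant.

## Synthetic area curves

Subject-level imaging data are generally unavailable, so cohorts are
synthesized. Each chamber's area over the normalized cycle (t = 0 at end
diastole) is a piecewise half-cosine interpolant through landmark areas:
end diastole `a_ed` (t = 0 and 1), end systole `a_es` (t_es), mid diastasis
`a_dd` (t_dd), a diastasis plateau to the atrial-kick onset (t_ak), then a
return to `a_ed`. Half-cosine easing was chosen over splines because each
segment is monotone between its landmarks, C¹ at the knots, and has a
closed-form midpoint value (v0+v1)/2 — which makes curve behaviour provable
in tests. The sampling grid is the uniform frame grid (default 30 frames,
the usual cine temporal resolution) merged with the landmark times, so
interpolation is exact at landmarks.

Timing defaults. The endocardial VSA crosses above the ASA at
t_cross = 0.53 of the cycle and remains above for 75% of diastole; these
two facts fix end systole at t_es = 1 − 0.47/0.75 ≈ 0.3733. Diastasis
midpoint (0.70) and atrial-kick onset (0.90) are chosen to give the
familiar plateau; they are configuration, not data.

Area-level defaults (cm²): ASA (14, 20, 16), VSA_endo (26, 12, 23.7),
VSA_epi (45, 38, 41.4) at (a_ed, a_es, a_dd). Only the mid-diastasis
differences — 7.7 cm² endocardial, 25.4 cm² epicardial above the atrium —
enter the force model; absolute levels are plausible healthy-adult values
and freely configurable.

The population-mean endocardial curve is *anchored*: an extra knot pins it
to the ASA value exactly at t_cross, making the 75%-of-diastole statement
exact rather than approximate on the mean curves.

Between-subject variability is a per-chamber level effect: one zero-mean
normal draw per chamber shifts all three landmarks together (defaults: sd
4.4 cm² endocardial, 7.3 cm² epicardial, 0 atrial — the printed
diastasis-difference SEMs of 1.4 and 2.3 cm² times √10 for the n = 10
design). Draws violating geometry (non-positive areas, endocardium
escaping the epicardium) are redrawn, at most 100 times. Each subject is
anchored at the population crossover when its drawn landmarks permit; when
they do not (about the lowest decile of endocardial draws), the subject
keeps the natural crossover its own landmarks imply rather than being
rejected — rejection would truncate the configured sd, and discordant
subjects do occur in real cohorts. Per-subject randomness comes from
`default_rng((seed, subject_index))`, so any subject is reproducible in
isolation.

What the generator does **not** emulate: heart-rate and phase-duration
variability (all subjects share the phase landmarks), within-subject
measurement noise, segmentation bias, atrial-appendage shape, and any
correlation between chamber sizes beyond the shared landmarks. Passing
tests therefore demonstrate the force pipeline and its calibration to
cohort-level summary statistics, not fidelity to individual cine
measurements.

## Driving-force comparison

Peak driving force = (25 mN/g) × inertial load, with load = LV mass (125 g)
+ 75–275 g of blood and vessel roots = 200–400 g, giving 5–10 N. The
hydraulic fraction of a force range is the pair of extreme ratios
(fh_min/fd_max, fh_max/fd_min). The headline fraction uses whole-newton
hydraulic forces (1 N and 3 N with default landmarks), reproducing the
conventional 10–60% band; the unrounded ratio is always reported alongside
so no precision is lost.

## Piston-rig simulation

The physical analog is a hollow piston with a small "atrial" end (default
10 cm²) and a large "ventricular" end (17.3 cm²) in a sealed two-chamber
housing pressurized by a water column (h₀ = 1.4 m). Equal pressure on
unequal faces gives a static force ρ·g·h·(A_large − A_small) ≈ 10 N toward
the small chamber. Dynamics are a 1-d rigid body between two stops:

    m·dv/dt = ρ·g·h(x)·ΔA − f_pull(t) − c·v

Column-height feedback is kept, but as an algebraic constraint rather than
a third ODE state: moving the piston by dx draws ΔA·dx from the standpipe,
so h + ΔA·x/a_column is invariant and volume conservation holds to machine
precision by construction. Setting `a_column` very large recovers the
constant-pressure limit. Piston mass (0.5 kg), damping (50 N·s/m, lumping
conduit and seal losses) and travel (30 mm) are bench-plausible inventions,
exposed in the `rig` config block, since only the column height and the
qualitative behaviour are externally constrained.

Numerics: classical fixed-step RK4 (default dt = 10⁻⁴ s — the dynamics are
non-stiff with a velocity relaxation time m/c = 10 ms, and a fixed step
keeps trajectories bit-reproducible); stop contact is perfectly inelastic
(position clamped, velocity zeroed — restitution is unconstrained by the
apparatus and the observed behaviour is the piston coming to rest); while
the net force presses the piston into a stop it is held there. The energy
audit in the tests checks that damping losses plus kinetic energy never
exceed the hydrostatic energy released by the column, the difference being
absorbed by the stops.

## Cohort statistics

Paired VSA-vs-ASA comparisons use the exact Wilcoxon signed-rank test:
zero differences dropped before ranking (Wilcoxon's original procedure),
average ranks for ties, W⁺ = sum of positive-difference ranks, and a null
distribution obtained by enumerating all 2ⁿ sign assignments (capped at
n = 15; no asymptotic fallback, since exactness at n ≈ 10 is the point).
The two-sided p doubles the smaller of P(W ≤ w) and P(W ≥ w), capped at 1 —
one of several doubling conventions in circulation, chosen for
reproducibility and verified in the tests against an independent
brute-force enumeration and against scipy's exact mode. Summaries are
mean ± SEM (sample sd / √n). On fully concordant data at n = 10 the exact
test gives p = 2/1024 ≈ 0.002; observed p-values near 0.02 in comparable
cohorts imply some discordant subjects, which the generator's unanchored
fallback can produce — p-values are therefore treated as descriptive
outputs, not calibration targets.

## Pipeline and reporting

`run_pipeline` is deterministic given the seed and config; the JSON report
carries provenance (seed, SHA-256 of the resolved config, package version,
schema version). Reported values follow clinical rounding — forces to
0.1 N, areas to 0.1 cm², fractions to whole percent — with unrounded
values (default 6 decimals) retained alongside. Non-finite summary values
(e.g. the SEM of a single-subject cohort) serialize as null.

## Problem sizes and known limitations

Default analyses run at the study design they emulate: 10 subjects,
30 frames per cycle; the rig integrates 1 s at dt = 10⁻⁴ s; calibration
properties are checked on 100–200-subject cohorts. The whole suite runs in
a few seconds.

Limitations: the generator's phase landmarks are shared across subjects;
the seeded n = 10 cohort is one random draw, so its sample SEMs can sit
well off the population values even though the means stay within one SEM
(the default seed's endocardial draw happens to be such a case); the
piston model lumps all fluid losses into linear damping and ignores
conduit inertance and hose elasticity; and the force model deliberately
says nothing about how hydraulic and myocardial restoring forces partition
during early filling.
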