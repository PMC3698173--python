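# Methods

## The physical model

`asterdrag` simulates the migration of a fertilized egg's sperm aster — the
centrosome plus male pronucleus and its radial microtubule array — toward
the cell centre, driven solely by the hydrodynamic drag on motor-hauled
cargoes. The assumptions, in decreasing order of importance:

- **Quasi-static force balance.** Inertia is irrelevant at cellular Reynolds
  numbers, so at every instant the net force on the aster is zero and the
  centrosome velocity is the algebraic root of the balance equation. No
  force–velocity model of the motors is needed: whatever the number of
  motors per cargo or the shape of their force–velocity relation, the force
  they transmit to the microtubule equals the Stokes drag on the cargo,
  $6\pi\eta_v R_v\,|\vec v_\text{cargo,cyto}|$. The cargo speed along the
  track, $v_{vm}$, is prescribed (motors are load-insensitive by
  construction); the per-vesicle force on the rod is the vector-exact
  reaction $6\pi\eta_v R_v(v_{vm}\hat e_i - u\hat x)$ projected on the axis,
  which avoids the sign ambiguities of scalar "±" shorthand.
- **Rigid, straight microtubules with fixed directions.** Rods co-translate
  with the centrosome; no bending, catastrophe or dynamic instability. Each
  rod grows at a constant polymerization rate and is clamped when its tip
  reaches the cell wall. The cytosol flows *through* the aster, so the aster
  drag is the sum of per-rod slender-body coefficients, not the drag of an
  equivalent sphere — this is why a 10× change in rod number changes both
  the drag and the pulling force by the same factor and leaves the dynamics
  unchanged.
- **Continuous cargo coverage.** Vesicle counts $n_i=\rho L_i$ are real
  numbers: the model describes average behaviour, not single-cargo
  stochasticity. Only minus-end (centrosome-directed) transport is included.
- **Two effective viscosities, one ratio.** The cargoes feel $\eta_v$, the
  much larger aster feels $\eta_c$; dividing the balance by $\eta_v$ leaves
  the single parameter $r=\eta_c/\eta_v$. Absolute viscosities never enter,
  and the code stores only the ratio.
- **Motion confined to the centring axis.** Transverse force components
  cancel on average by symmetry and are discarded.

## Parameters

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| cell radius | — | 500 | µm | large-embryo geometry (1000 µm diameter) |
| centrosome radius | $R_c$ | 2 | µm | centrosome + pronucleus as one sphere |
| initial wall distance | — | 4 | µm | sperm entry point near the cortex |
| vesicle radius | $R_v$ | 0.05 | µm | 100 nm cargo, the small end of the observed 100–1000 nm range (a deliberate worst case: force scales with $R_v$) |
| cargo speed on track | $v_{vm}$ | 2 | µm/s | upper end of measured organelle transport speeds (0.5–2 µm/s) |
| cargo linear density | $\rho$ | 2 | /µm | deliberately sparse; force scales linearly with $\rho$ |
| viscosity ratio | $r$ | 3 | — | unmeasured; swept 2–6 in the studies |
| polymerization rate | — | 0.25 | µm/s | measured aster growth rate (15 µm/min) |
| microtubule count | — | 100 | — | dynamics are count-invariant (tested); 100 keeps runs fast |
| seed rod length | — | 2 | µm | nascent aster |
| microtubule radius | $a$ | 0.0125 | µm | 25 nm diameter; enters only logarithmically |
| time step | $dt$ | 0.5 | s | explicit Euler; speeds ~0.1 µm/s make the per-step motion ≪ all geometric scales |
| duration | — | 2700 | s | the 45-minute observation window |

The slender-body coefficients use the classical translating-rod constants
$\zeta_\parallel = 2\pi L/(\ln(2L/a)-\tfrac12)$,
$\zeta_\perp = 4\pi L/(\ln(2L/a)+\tfrac12)$; both additive constants are
keyword-configurable for sensitivity checks (the dependence is
logarithmic).

## The aster generator

Rod directions are drawn once per run from a seeded `numpy` generator and
held fixed. By default (`aster_dimension = 2`) they are isotropic **in the
equatorial plane** containing the centring axis — the plane in which the
embryo simulation is posed — so the axis cosines follow the arcsine law
(density peaked at ±1). The planar aster reproduces the observed embryo
phenomenology: the velocity reaches ~80% of its maximum within the first
five minutes and the 45-minute displacement is ~350 µm. A fully spherical
option (`aster_dimension = 3`, axis cosines uniform on [−1, 1]) is retained;
it weights oblique rods more heavily, which slows the build-up of the
near/far asymmetry (80% of max speed only after ~10 min) without changing
any qualitative conclusion.

What the generator deliberately does **not** emulate: microtubule dynamic
instability (lengths are deterministic given the geometry), cargo number
fluctuations, bidirectional cargo motion, rod bending near the cortex, and
off-axis centrosome excursions. Passing tests therefore validate the
average force-balance mechanism in an idealized geometry, not the
stochastic fine structure of real aster growth.

## Numerical and design choices

- **Velocity solve.** The balance is linear in $u$ with a strictly positive
  denominator, so the closed form is exact; an independent bisection
  root-find of the residual agrees to 1e−10 relative (tested on random
  states).
- **Growth and clamping.** Each step, every rod length advances by
  `rate × dt` and is capped at the exact centrosome-to-wall distance along
  its direction, $L^\* = s\,c + \sqrt{s^2c^2 + R^2 - s^2}$ (the positive
  root of $|\vec p + L\hat e| = R$). The cap is re-evaluated at the current
  centrosome position, so near-side rods clamped at the wall **resume
  growing** as the centrosome departs. The alternative (rods frozen forever
  at first contact) was implemented and rejected: it predicts ~790 µm of
  motion in 45 minutes (~290 nm/s), far outside the observed 300–500 µm and
  100–200 nm/s. Rods never depolymerize, but a far-side rod pinned at the
  wall shortens with the receding cap as the centrosome advances.
- **Wall-contact bookkeeping.** "Far" versus "near" cortical contact is
  classified by the hemisphere of the touching tip (axis coordinate of the
  tip above or below the cell centre), not by the sign of the rod's axis
  cosine: rods nearly perpendicular to the axis meet the side wall close to
  the near hemisphere long before anything reaches the far cortical region,
  and counting those as "far contact" would make the contact-ordering
  observable meaningless.
- **Termination and safety.** Runs always integrate to the configured
  duration; there is no early stop at the centre. If the centrosome
  overshoots, the sign of $\sum n_ic_i$ reverses the force naturally. A
  positional clamp at $|s| = R - R_c$ exists as a logged safety guard and
  never triggers for realistic parameters.
- **Degenerate inputs.** Zero cargo speed is allowed (a no-transport
  control; the velocity is exactly zero). Zero-duration runs return the
  single initial sample. Empty asters, non-unit directions, nonpositive
  lengths/radii and rods short enough to break the slender-body logarithm
  raise typed errors naming the offending field.

## Study drivers and problem sizes

The ensemble/sweep drivers run one simulation per (value, seed) pair and
aggregate mean ± sd per value. Default study sizes: ten seeds for the
baseline ensemble averages, three seeds per grid point for the
viscosity-ratio (ratios 2–6, 100 and 200 nm cargoes, 3 h horizon so slow
runs still reach 300 µm) and polymerization-rate (150–450 nm/s at viscosity
ratio 5, 2 h horizon) studies. A 45-minute run is 5 400 explicit-Euler
steps over 100 rods (~0.1 s), so the full study suite completes in well
under a minute on one core.

## Known limitations

- The crossover of the contact-ordering observable (whether a far-side rod
  touches the cortex before the 300 µm displacement completes) sits very
  close to the 250 nm/s growth rate at viscosity ratio 5; its position
  shifts by a few percent with the aster realization and with the exact
  treatment of the cargo back-reaction term, so the ordering *at exactly*
  250 nm/s is not a robust prediction of this implementation, while the
  trend (faster growth ⇒ contact progressively earlier relative to
  centring) is.
- The loading diagnostic (the lab-frame construction
  $\Delta = 2v_c - v^R_{lab} - v^L_{lab}$, zero for load-insensitive motors,
  positive for load-sensitive ones) is a measurement prescription for
  experimental data; the simulator's motors are load-insensitive by
  construction, so the model only verifies $\Delta = 0$, and the formula is
  a reconstruction from its documented sign behaviour.
- Effective viscosities stand in for the cytoplasm's non-Newtonian, size-
  and rate-dependent rheology; conclusions should be read as statements
  about the ratio $r$, not about absolute drag levels.
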