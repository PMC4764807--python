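# Methods

## Model

The medium is the two-variable Barkley caricature of cardiac excitation on
a regular 3D grid,

    du/dt = (1/eps) u (1 - u) (u - (v + b)/a) + div(grad u),
    dv/dt = u - v,

with `u` the fast activator (membrane potential) and `v` the slow recovery
variable.  The diffusion constant is fixed at 1 and sets the space unit.
Kinetics defaults are `a = 0.9`, `b = 0.08`, `eps = 0.02`: the spiral wave
rotates rigidly and scroll-wave filaments have positive tension, i.e. a
closed filament loop shrinks ("collapsing scroll rings" regime).  The rest
state `u = v = 0` is a fixed point, as is the fully excited `u = v = 1`.

## Obstacle and electric-field coupling (phase field)

A non-conducting sphere of radius `R` is embedded with the phase-field
method: a smooth indicator

    phi(r) = (1 + tanh((|r - c| - R)/xi)) / 2

(0 inside, 1 in tissue, interface width `xi = 2 dx` by default) replaces
the sharp boundary, and the diffusion operator becomes

    (1/phi) div(phi (grad u - E)),

evaluated in flux form with face-averaged phi.  In the sharp-interface
limit this enforces the Neumann condition `n . grad u = n . E` on the
obstacle surface, where `E(t)` is the applied, spatially uniform electric
field and `n` the outward obstacle normal: the field redistributes
membrane potential around the obstacle, depolarizing one flank and
hyperpolarizing the opposite one (the virtual-electrode pattern; a static
field along +x depolarizes the -x flank).  With `E = 0` it reduces to the
no-flux condition on the curved surface; a mirrored ghost layer imposes
no-flux on the outer box.

Numerical guards (all three matter; each was isolated against a failure
mode of the forced boundary layer):

* Nodes with `phi < phi_floor = 0.002` are obstacle interior, held at
  `u = v = 0` (guards the 1/phi division).
* The reaction kinetics run where `phi >= kinetics_phi_min = 0.05`.  The
  deepest interface tail (`phi` in [0.002, 0.05)) evolves by the
  phi-weighted diffusion + forcing alone, as a passive linear extension
  with `v` frozen.  Keeping that tail active (rather than clamped to
  rest) is what carries the forcing source accurately: clamping it
  degrades agreement with an independent ghost-node discretization from
  a few percent to tens of percent (see the boundary-oracle tests).
* The recovery variable is clamped to `v_clamp = (-1, 1.5)`.  Normal
  dynamics keep `v` within roughly [0, 1], so the clamp never binds
  there; under a sustained strong surface forcing, however, rim nodes
  enter the cubic's unbounded branch — `u > 1` with `v` chasing the
  moving threshold `(v+b)/a`, which has no finite fixed point for
  `a < 1` — and the clamp arrests exactly that mode.  With it, every
  waveform studied here is stable through `E0 = 7`.
* Inside the forced boundary layer `u` legitimately exceeds 1 (the field
  holds a depolarized rim); the runaway detector therefore uses a loose
  amplitude bound (|u| > 2.5) plus finiteness.

## Time stepping

Forward Euler with the 7-point Laplacian.  The stability bound is the
diffusive `dt <= dx^2/6`; the default is `dt = min(0.8 dx^2/6, 0.005)`,
i.e. 0.005 at the default `dx = 0.25`.  The 0.005 cap is set by the forced
boundary layer: where the field holds `u ~ 1.3-1.6` the cubic stiffens to
`|df/du| ~ (3/eps) u^2`, and 0.005 keeps the explicit update stable for
field strengths up to `E0 ~ 7`.  Halving `dt` moves the measured scroll
rotation frequency by well under 1% (asserted in the suite).  The hot loop
is a single fused numba kernel (branch-free interior, ping-ponged
buffers); all scenario runs below are exact re-runs given a configuration
— no randomness anywhere in the pipeline.

## Field waveforms

All fields are spatially uniform and horizontal:

* pulsed DC (PDCEF): `E0 x_hat` during the first `d` time units of each
  period `2 pi / omega_e`;
* AC (ACEF): `E0 cos(omega_e t) x_hat`;
* circularly polarized (CPEF): `E0 (cos omega_e t, sin omega_e t, 0)`,
  rotating about z with constant magnitude.

On the sphere the surface forcing `n . E` has temporal extremum
`E0 sin(theta) |cos(phi_az)|` for the x-directed waveforms but
`E0 sin(theta)` for CPEF: the rotating depolarization spot sweeps the
whole equator instead of acting at two antipodal spots.  This
azimuth-independence is the structural reason the rotating field can pace
the obstacle faster than the other two.

## Synthetic initial states

No external data exist; all states are generated:

* quiescent medium (`u = v = 0`);
* pinned scroll: a cross-field seed (excited half-space broken against a
  `v = a/2` refractory block), uniform in z, centered on the obstacle,
  relaxed field-free for >= 5 rotation periods (default 20 time units),
  then verified: the filament (u/v isosurface intersection) spans z and
  touches the obstacle within 2 dx.  The seed's chirality is chosen
  co-rotating with the CPEF sense (counterclockwise about +z); chirality
  is irrelevant for every quiescent-medium measurement but matters for
  unpinning, where the rotating depolarization spot must chase the
  recovered wake behind the scroll arm rather than collide with its
  refractory tail.
* scroll ring: an axisymmetric broken-front seed (excited cylinder top
  half, refractory collar outside the ring radius) in an obstacle-free
  box.  Its filament is a closed planar loop that shrinks under positive
  tension and collapses; collapsing rings also drift along their symmetry
  axis, which is physical, so tests assert planarity and monotone
  shrinkage rather than a fixed plane.

These generators emulate the study conditions only: rigid rotation, a
single untwisted filament, homogeneous isotropic tissue.  They do not
emulate ionic-model restitution, anisotropy, or tissue heterogeneity
beyond the one obstacle, so passing tests say nothing about realistic
cardiac geometry.

## Measurements

* Wave frequencies: `u(t)` is sampled every 0.05 time units at probes
  10 dx outside the obstacle surface (six, one per axis direction);
  activations are upward crossings of `u = 0.5`, the first two are
  discarded as transient, and `omega = 2 pi /` mean inter-activation
  interval (>= 4 crossings required).  A wave train is "sound" (a regular,
  unbroken expanding sphere) when the interval CV is below 10% and all six
  probes fire each cycle (counts equal up to an edge effect of one).
* Filaments: intersection of the `u = 0.5` and `v = a/2 - b` isosurfaces;
  every grid-cell face where both isolines cross contributes the bilinear
  intersection point (2D Newton solve), excluding faces inside the
  obstacle.  Points are unordered; distances to the obstacle surface and
  to the success box are derived per sample.
* Removal classification: filament sampled every 1 time unit; detachment
  = first sample with no point within 1 dx of the surface; removal =
  first sample with no point inside the obstacle-centered success box
  (default half-width 2R); success = removal within 500 time units.
* Quiescence: max `u` over tissue nodes below 0.01.

## Scenario scales

Quiescent-medium experiments (wave emission, frequency scans) run on a
60^3 box (15 space units) at `dx = 0.25` with `R = 3` (12 dx) and
`xi = 2 dx`, probe scans over `omega_e` in 0.25 steps from 2.0, and
50-120 time units per emission run (enough for >= 6 activations above
the discarded transient; pulsed-DC emission locks to subharmonics of the
pulse rate and needs the longer windows).

The unpinning scenarios use their own reference configuration
(`experiments.removal_reference_setup`): a laterally elongated
120 x 120 x 60 box (30 x 30 x 15 units) with `xi = 4 dx`.  Both changes
are load-bearing and were isolated systematically:

* interface width: the CPEF-driven nucleation that must persist against
  the pinned scroll's own waves depends on the thickness of the forced
  rim layer; at `xi = 2 dx` the drive only produces a detach/re-pin
  limit cycle at every amplitude tried, while `xi = 4 dx` sustains it.
  (Conversely the quiescent-medium thresholds match the study's stated
  field amplitudes at `2 dx`, which is why the two experiment families
  keep separate widths — the surface forcing peaks at `2 E0 (1-phi)/xi`,
  so amplitude thresholds shift with the interface width.)
* lateral room: near a no-flux wall a filament interacts with its mirror
  image; in a cubic 60^3 box the wall sits about half a scroll
  wavelength from the obstacle and the driven filament is annihilated
  apex-first at the wall and re-pins.  With doubled lateral extent the
  filament clears the success box (half-width 2R) instead.

In that configuration the co-rotating CPEF at the saturating amplitude
(E0 = 1.8, omega_e = 3.5) detaches the filament within a few time units
and drives it out of the success box in about a hundred.

## Design choices

* Forcing sign: the flux form `div(phi(grad u - E))` fixes the sign of
  the forcing term; the resulting depolarization pattern (a +x field
  depolarizes the -x flank) is locked by a regression test.
* PDCEF "frequency" means pulse-repetition angular frequency, so PDCEF
  and AC/CPEF scans share an axis; pulses are rectangular with instant
  on/off and the AC/CPEF initial phase is zero at field onset.
* Isovalues for filament detection (`u = 0.5`, `v = a/2 - b`) sit
  mid-range on the rigidly rotating spiral, making the intersection
  robust; both are configurable.
* The success box is reported with every outcome; the default half-width
  2R is a declared convention, not a fitted value.

## Limitations

* The model is a two-variable caricature; nothing here is a quantitative
  statement about ionic cardiac tissue.
* The emission-rate ceiling of the medium (set by near-obstacle
  refractoriness) sits only a few percent above the pinned scroll's
  rotation frequency — the scroll rotates close to the fastest
  sustainable wave train — so unpinning-by-frequency-competition
  operates with a thin margin everywhere.  Two consequences at this
  scale: the scroll driven out of the success box is not annihilated
  (transient wave break keeps re-seeding filaments while the field is
  on, and with the field off the freed filament straightens and re-pins
  under its positive tension — the premature-switch-off behaviour), and
  unpinning works only when the field co-rotates with the scroll, since
  the rotating depolarization spot must chase the recovered wake behind
  the scroll arm.
* Pulsed-DC forcing at E0 = 2 sits near its nucleation threshold here:
  it emits at most pulse frequencies but the trains are regular enough
  to classify as sound only in part of the band, so the measured
  sound-threshold for pulsed DC is coarser than for the rotating field.
* Explicit Euler and the coarse `dx = 0.25` under-resolve the excitation
  front thickness; frequencies are dx-converged to well under 1% but
  breakup thresholds (the "sound wave" boundary) are resolution-
  sensitive.
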