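# scrollwave

Simulation and analysis of **scroll-wave unpinning by external electric
fields** in a generic three-dimensional excitable medium.

Rotating waves (2D spirals, 3D scroll waves) anchored to non-conducting
heterogeneities — scar tissue, blood vessels — sustain dangerous cardiac
arrhythmias, and anchored waves are notoriously hard to terminate without
large shocks.  A low-amplitude electric field offers a gentler route: at a
conductivity heterogeneity the field redistributes membrane potential
(`du/dn = n·E` on the obstacle surface), creating a depolarized/
hyperpolarized virtual-electrode pair that can nucleate new waves — *wave
emission from heterogeneities* (WEH).  If the obstacle can be paced faster
than the pinned scroll rotates, the emitted waves invade its territory and
drive the filament off the obstacle and out of the tissue.

This package implements the full computational study for the Barkley
medium

```
du/dt = (1/ε) u (1−u) (u − (v+b)/a) + ∇·(∇u),    dv/dt = u − v,
```

with `a = 0.9`, `b = 0.08`, `ε = 0.02` (rigid rotation, positive filament
tension), a spherical obstacle embedded by the phase-field method so that
the field enters through `(1/φ)∇·(φ(∇u − E))`, and three waveforms:
pulsed DC (PDCEF), AC (ACEF) and circularly polarized (CPEF,
`E0 (cos ωe t, sin ωe t, 0)`).  The analysis layer measures activation
frequencies at probes, detects scroll filaments as u/v isosurface
intersections, and classifies detachment/removal; scenario runners
reproduce the computational experiments: wave emission in a quiescent
medium, frequency-response scans of the three waveforms against the
pinned scroll's rotation frequency, the CPEF removal time course, and the
(E0, ωe) removal phase diagram.

The central quantitative result it reproduces: **only the circularly
polarized field emits well-formed spherical waves faster than the pinned
scroll rotates** — the x-directed waveforms reach `E0 sinθ |cosφ|` on the
obstacle surface while CPEF reaches `E0 sinθ` at *every* azimuth — and a
CPEF from that regime detaches the filament within a few time units and
sweeps it out of the obstacle-centered success box well within the
500-time-unit budget.

## Worked example

```python
>>> import scrollwave as sw
>>> from scrollwave.experiments import measure_scroll_frequency
>>> params = sw.default_params(grid=60)            # 60^3 nodes, dx = 0.25
>>> domain = sw.default_domain(params, radius=3.0) # spherical obstacle
>>> pinned = sw.pinned_scroll_init(params, domain)
>>> omega_scroll, cv = measure_scroll_frequency(pinned, domain, params)
>>> print(f"{omega_scroll:.3f} (CV {cv:.3f})")
1.709 (CV 0.002)
>>> out = sw.run_weh_quiescent(sw.FieldSpec.cpef(1.8, 3.75), params, domain)
>>> print(out.sound, f"{out.omega_wave:.3f}")
True 1.819
```

The pinned scroll rotates at `ω_scroll ≈ 1.71` radians per time unit
(interval coefficient of variation 0.2%: stationary rotation), and a
circularly polarized field at `ωe = 3.75` paces the obstacle with a sound
(regular, unbroken) spherical wave train at `ω_wave ≈ 1.82 > ω_scroll` —
the regime in which removal is possible.  The same call with
`sw.FieldSpec.pdcef(2.0, 3.75, 0.1)` yields `ω_wave ≈ 0.58`: pulsed DC
cannot outpace the scroll at any scanned frequency.

The `examples/` directory holds one short script per capability (wave
emission, surface forcing, pinned-scroll preparation, frequency scans,
removal, phase diagram); a thin CLI (`scrollwave weh|freq-scan|removal|
phase-diagram|make-state`) wraps the same runners for shell use.

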