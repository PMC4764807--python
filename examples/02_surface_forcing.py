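"""Analytic surface forcing n.E of the three field waveforms.

The field acts on the medium only through the Neumann condition
n.grad(u) = n.E on the obstacle surface.  This example evaluates the
temporal extremum of |n.E| over the sphere for each waveform and shows why
the rotating field is special: its reach is azimuth-independent.
"""

import numpy as np

import scrollwave as sw

E0 = 2.0
pdcef = sw.FieldSpec.pdcef(E0, 3.75, 0.1)
acef = sw.FieldSpec.acef(E0, 3.75)
cpef = sw.FieldSpec.cpef(E0, 3.75)

print("theta    phi_az | PDCEF   ACEF    CPEF   (max_t |n.E|)")
for theta in (np.pi / 2, np.pi / 4):
    for phi_az in (0.0, np.pi / 4, np.pi / 2):
        row = [sw.surface_forcing_extremum(s, theta, phi_az) for s in (pdcef, acef, cpef)]
        print(f"{theta:6.3f} {phi_az:7.3f} | " + "  ".join(f"{v:5.3f}" for v in row))

# The x-directed waveforms reach E0 sin(theta)|cos(phi_az)|: they act only
# near two antipodal spots of the equator and are blind to phi_az = pi/2.
# The rotating field reaches E0 sin(theta) at every azimuth -- its
# depolarizing spot sweeps the whole equator once per field period, which
# is what lets it outrun a pinned scroll wave.
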