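"""Success region of pinned-scroll removal in the (E0, omega_e) plane.

Runs one removal attempt per grid cell (each up to 500 time units, so a
full grid is hours of compute on one core; shrink the lists for a quick
look).  Cells reuse the same relaxed pinned state.
"""

import scrollwave as sw
from scrollwave.experiments import removal_reference_setup, run_phase_diagram

params, domain = removal_reference_setup()
pinned = sw.pinned_scroll_init(params, domain, sw.ScrollInitSpec(relaxation_time=20.0))

E0_values = [1.6, 2.0, 2.4, 2.8]
omega_values = [3.0, 3.25, 3.5, 3.75]

result = run_phase_diagram(E0_values, omega_values, params, domain, pinned,
                           t_limit=500.0)
table = result.table.pivot(index="E0", columns="omega_e", values="success")
print(table)
print()
per_e0 = result.table.groupby("E0")["success"].sum()
print("successful omega_e cells per E0:")
print(per_e0)

# True cells mark (E0, omega_e) combinations whose CPEF drives the
# filament out of the obstacle-centered success box within 500 time
# units; the count per row is the measure of the successful interval.
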