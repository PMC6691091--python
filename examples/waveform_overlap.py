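"""1T1R pulse overlap: which pre/post timings SET, RESET or do nothing.

Sweeps the post-minus-pre spike lag and classifies each overlap from the
peak cell voltage inside the matching gate window.  The analytic extremes
are V_BL+ + |V_SL-| = 1.6 V (SET) and V_SL+ + |V_BL-| = 2.3 V (RESET);
an isolated pulse only ever reaches 1.3 V and never programs the device.
"""

import numpy as np

from memstdp import PulseSpec, classify_operation

pulses = PulseSpec()
print("pulse defaults:", pulses, "\n")

print(f"{'dt (ns)':>8} {'peak SET (V)':>13} {'peak RESET (V)':>15} {'op':>6}")
for dt in (-400, -200, -100, -30, -5, 5, 30, 100, 200, 400, 1000):
    r = classify_operation(pulses, dt)
    print(f"{dt:8d} {r.peak_set_voltage:13.2f} {r.peak_reset_magnitude:15.2f} "
          f"{r.operation:>6}")

dts = np.arange(-600, 601, 5)
ops = [classify_operation(pulses, float(dt)).operation for dt in dts]
set_rng = [dt for dt, op in zip(dts, ops) if op == "SET"]
reset_rng = [dt for dt, op in zip(dts, ops) if op == "RESET"]
print(f"\nSET window:   dt in [{min(set_rng)}, {max(set_rng)}] ns "
      "(post just after pre -> potentiation)")
print(f"RESET window: dt in [{min(reset_rng)}, {max(reset_rng)}] ns "
      "(post just before pre -> depression)")
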