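"""Look inside the clamp controller: the reference trajectory and the
discrete PID updates that steer the glucose infusion."""

import numpy as np

import hypoclamp as hc
from hypoclamp.controller import (ControllerState, pid_step,
                                  reference_trajectory)

protocol = hc.ProtocolConfig()
config = hc.ControllerConfig()

# the reference: linear descent to 2.5 at t150, 20-min hold, restoration
ref = reference_trajectory(protocol, g_at_insulin_start=5.5, config=config)
for t in (90, 120, 150, 160, 170, 200):
    print(f"reference at t={t:3d}: "
          f"{np.interp(t, ref.times, ref.values):.2f} mmol/l")

# a few hand-driven PID updates: glucose runs 0.3 mmol/l below reference
print("\nPID response to a sustained -0.3 mmol/l tracking error:")
state = ControllerState(phase="hold")
for k in range(4):
    gir, state = pid_step(state, 2.2, 2.5, config, dt=5.0)
    print(f"  update {k}: GIR = {gir:.2f} mg/kg/min "
          f"(integral {state.integral:.2f})")

# The proportional term answers immediately, the integral ramps the
# infusion while the error persists, and the output is always clipped to
# [0, GIR_max] -- the controller can only add glucose, never remove it.
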