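"""Hill curves and via-point geometry at the standing reference posture.

Prints the three fitted curves at landmark abscissae and, for each muscle,
the posed path length l_mt, the sagittal moment arm h about the ankle, the
out-of-plane angle phi_m, and the rigid-tendon fiber state.
"""

import numpy as np

from ankledyn import (
    JointConfiguration,
    build_reference_subject,
    f_active,
    f_passive,
    f_velocity,
    muscle_path_state,
    pennation,
)
from ankledyn.hill import fiber_length

print("f_active(l/l0):  0.7 -> %.3f   1.0 -> %.3f   1.3 -> %.3f"
      % (f_active(0.7), f_active(1.0), f_active(1.3)))
print("f_passive(l/l0): 1.0 -> %.2e  1.3 -> %.2e" % (f_passive(1.0), f_passive(1.3)))
print("f_velocity(v/vmax): -0.2 -> %.3f  0.0 -> %.3f  +0.2 -> %.3f"
      % (f_velocity(-0.2), f_velocity(0.0), f_velocity(0.2)))

subject = build_reference_subject()
print("\nstanding reference posture (ankle/knee deviations = 0):")
print("muscle    l_mt[mm]   h[mm]  phi[rad]  l_m[mm]  l_m/l_m0  theta_m[rad]")
for name, muscle in subject.muscles.items():
    st = muscle_path_state(muscle, subject, JointConfiguration())
    l_m = fiber_length(st.total_length, muscle)
    th = pennation(l_m, muscle.optimal_fiber_length, muscle.pennation_at_optimum)
    print(f"{name:8s}  {st.total_length:8.1f}  {st.moment_arm:6.1f}  {st.sagittal_angle:8.4f}"
          f"  {l_m:7.1f}  {l_m / muscle.optimal_fiber_length:8.3f}  {th:10.3f}")
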