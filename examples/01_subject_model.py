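"""Build the reference subject and scale it to a different anthropometry.

The reference subject (73 kg, 1.70 m, 10-kg waist load) carries the four
ankle muscles with their Hill constants and via-point paths, and the
four-segment inertial parameters derived from stature/mass percentages.
"""

from ankledyn import build_reference_subject, scale_subject

subject = build_reference_subject()
print("reference subject: %.0f kg, %.2f m, +%.0f kg waist load"
      % (subject.body_mass, subject.height, subject.load_mass))
for name, seg in subject.segments.items():
    print(f"  {name:5s}: length {seg.length:.4f} m, mass {seg.mass:6.2f} kg, "
          f"k {seg.com_factor:.3f}, J {seg.inertia:.4f} kg m^2")
for name, m in subject.muscles.items():
    print(f"  {name:8s}: F_m0 {m.peak_force:6.0f} N, l_m0 {m.optimal_fiber_length:4.0f} mm, "
          f"l_t {m.tendon_length:4.0f} mm, theta0 {m.pennation_at_optimum:.3f} rad, "
          f"{len(m.path)} path points")

tall = scale_subject(subject, body_mass=85.0, height=1.85)
print("\nscaled to 85 kg / 1.85 m:")
print(f"  soleus F_m0: {tall.muscles['soleus'].peak_force:.1f} N "
      "(peak force scales with body mass)")
print(f"  shank length: {tall.segments['shank'].length:.4f} m "
      "(lengths scale with stature)")
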