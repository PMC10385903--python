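# Reference subject configuration: a 26-year-old male, 73 kg, 1.70 m,
# carrying a 10-kg waist load during the sit-to-stand trials.
#
# Muscle rows give the Hill constants (peak isometric force, optimal fiber
# length, tendon slack length, pennation at optimum) and the 3-D polyline
# path of each muscle-tendon unit from origin to insertion.  Coordinates are
# millimetres in the ankle joint frame (X anterior, Y proximal, Z lateral)
# except where frame: knee, in which case they are expressed in the knee
# joint frame and are mapped into the ankle frame with
# knee_origin_in_ankle_frame_mm at the standing reference posture.
#
# Segment rows give body-segment inertial parameters: segment length as a
# percentage of stature, segment mass as a percentage of whole-body mass,
# the centre-of-mass position factor along the segment, and the moment of
# inertia about the segment COM.

subject:
  mass_kg: 73.0
  height_m: 1.70
  load_kg: 10.0

knee_origin_in_ankle_frame_mm: [-11.2, 386.0, 0.0]

segments:
  foot:  {length_pct_height: 14.77, mass_pct_body: 3.6,  com_factor: 0.5,   inertia_kg_m2: 0.0044}
  shank: {length_pct_height: 23.86, mass_pct_body: 10.6, com_factor: 0.567, inertia_kg_m2: 0.0385}
  thigh: {length_pct_height: 28.13, mass_pct_body: 22.7, com_factor: 0.567, inertia_kg_m2: 0.1987}
  HAT:   {length_pct_height: 50.17, mass_pct_body: 63.1, com_factor: 0.374, inertia_kg_m2: 0.9180}

muscles:
  tib_ant:
    peak_force_N: 831.0
    l_m0_mm: 93.0
    l_t_mm: 211.0
    theta0_rad: 0.087
    path:
      - {xyz_mm: [17.0, 253.0, 10.4],   frame: ankle, segment: shank}
      - {xyz_mm: [31.0, 33.0, -17.0],   frame: ankle, segment: shank}
      - {xyz_mm: [64.0, -22.7, -21.7],  frame: ankle, segment: foot}
  ext_dig:
    peak_force_N: 470.0
    l_m0_mm: 96.0
    l_t_mm: 325.0
    theta0_rad: 0.140
    path:
      - {xyz_mm: [2.8, 275.7, 26.4],    frame: ankle, segment: shank}
      - {xyz_mm: [27.3, 27.3, 6.6],     frame: ankle, segment: shank}
      - {xyz_mm: [40.6, -2.8, 7.5],     frame: ankle, segment: foot}
      - {xyz_mm: [164.0, -41.0, 32.1],  frame: ankle, segment: foot}
  med_gas:
    peak_force_N: 1432.0
    l_m0_mm: 57.0
    l_t_mm: 368.0
    theta0_rad: 0.300
    path:
      - {xyz_mm: [-2.8, 17.0, -22.6],   frame: knee,  segment: thigh}
      - {xyz_mm: [-13.0, 11.3, -24.5],  frame: knee,  segment: thigh}
      - {xyz_mm: [-46.0, -10.4, 2.8],   frame: ankle, segment: foot}
  soleus:
    peak_force_N: 3262.0
    l_m0_mm: 47.0
    l_t_mm: 236.0
    theta0_rad: 0.436
    path:
      - {xyz_mm: [-1.8, 252.0, 6.7],    frame: ankle, segment: shank}
      - {xyz_mm: [-46.0, -10.4, 2.8],   frame: ankle, segment: foot}

# Per-muscle RMS of the sEMG signal at maximum voluntary contraction, in mV.
# These are plausible surface-electrode values; the MVC protocol is a
# per-subject calibration input, not something the model derives.
emg:
  rms_mvc_mV:
    tib_ant: 0.45
    ext_dig: 0.35
    med_gas: 0.40
    soleus: 0.50
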