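# Packaged parameter fixtures for the two-layer arterial wall model.
# Units: radii/thicknesses mm, angles degrees, stiffnesses/tractions kPa,
# separation energy N/mm.
rabbit:
  # Rabbit carotid artery, two layers.
  materials:
    media:
      c: 1.5
      k1: 2.3632
      k2: 0.8393
      beta: 29.0
      T_c: 3.0
      G_c: 0.001
      du_c: 0.667
    adventitia:
      c: 0.15
      k1: 0.5620
      k2: 0.7112
      beta: 62.0
      T_c: 0.3
      G_c: 0.0001
      du_c: 0.667
  omega0:
    R_i: 1.430
    T_m: 0.260
    T_a: 0.130
    alpha: 160.0
  omega_r:
    # the alpha = 0 row below, which carries one more printed digit than
    # the coarser (0.739, 0.259, 0.120) statement of the same geometry
    r_i: 0.7395
    t_m: 0.2593
    t_a: 0.1197
  # Stress-free geometries recovering the same unloaded annulus at each
  # opening angle (columns: alpha, R_i, T_m, T_a).
  omega0_vs_alpha:
    - [0.0,   0.7395, 0.2593, 0.1197]
    - [40.0,  0.8472, 0.2595, 0.1221]
    - [80.0,  0.9858, 0.2597, 0.1246]
    - [120.0, 1.1708, 0.2599, 0.1272]
    - [160.0, 1.4300, 0.2600, 0.1300]
    - [200.0, 1.8191, 0.2601, 0.1329]

human_aorta:
  # Aged human thoracic aorta -- PROVISIONAL. The printed source table is
  # typographically ambiguous for the per-layer stiffness and fibre-angle
  # entries, so only unambiguous fields are stored; the rest are flagged
  # unparsed and no solver fixture is built from this entry.
  provisional: true
  alpha: 80.0
  T_c_over_c_media: 2.0
  materials:
    media:
      G_c: 0.001
      thickness_mm: 0.69
      R_i: 1.13
      c: unparsed
      k1: unparsed
      k2: unparsed
      beta: unparsed
    adventitia:
      G_c: 0.0001
      thickness_mm: 0.48
      c: unparsed
      k1: unparsed
      k2: unparsed
      beta: unparsed
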