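# Packaged index patient: 16-year-old with a Lenke 2B double thoracic
# pattern.  Amplitudes below are starting guesses; the fixture calibrates
# them so the measured angles hit the `targets` block.
total_height: 430.0
seed: 0
jitter_sigma: 0.0
kyphosis_amplitude: 17.0
lordosis_amplitude: 25.0
curves:
  - region: PT
    upper_end: T1
    apex: T3
    lower_end: T5
    side: left
    coronal_amplitude: 12.0
    apical_axial_rotation: 8.0
  - region: MT
    upper_end: T5
    apex: T8
    lower_end: T11
    side: right
    coronal_amplitude: 30.0
    apical_axial_rotation: 15.0
  - region: TL/L
    upper_end: T11
    apex: L2
    lower_end: L4
    side: left
    coronal_amplitude: 22.0
    apical_axial_rotation: 8.0
targets:
  PT: 51.0
  MT: 56.0
  TL/L: 38.0
  TK: 22.0
  LL: 44.0
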