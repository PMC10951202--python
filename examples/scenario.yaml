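# Packaged demo scenario: a small plate that runs the whole chain in seconds.
seed: 11
atlas:
  n_regions: 12
  shape: [256, 256]
cells_per_region: 60
mixtures:
  alpha: [2.0, 6.0, 2.0]
model:
  m_low: 40.0
  m_med: 100.0
  m_high: 180.0
  s_class: 10.0
  background: 20.0
  s_bg: 5.0
transform:
  max_rotation_deg: 8.0
  scale_range: [0.95, 1.05]
  max_translation_px: 10.0
  n_anchors: 4
  anchor_jitter_px: 2.0
dab:
  n_positive: 40
  n_hematoxylin: 150
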