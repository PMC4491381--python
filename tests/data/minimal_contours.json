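{
  "schema_version": 1,
  "slice_offset": 2,
  "n_slices": 1,
  "n_frames": 1,
  "ed_frame": 0,
  "es_frame": 0,
  "endo": [[[[11.0, 8.0], [10.1, 10.1], [8.0, 11.0], [5.9, 10.1], [5.0, 8.0], [5.9, 5.9], [8.0, 5.0], [10.1, 5.9]]]],
  "epi": [[[[13.0, 8.0], [11.5, 11.5], [8.0, 13.0], [4.5, 11.5], [3.0, 8.0], [4.5, 4.5], [8.0, 3.0], [11.5, 4.5]]]],
  "outflow_flags": [[[0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]]],
  "longaxis_displacement": [0]
}
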