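# Pinned extraction configuration.
# 107 features: shape-size 14, first-order 18, textural 75
# (GLCM 24, GLRLM 16, GLSZM 16, GLDM 14, NGTDM 5).
discretization:
  mode: fixed_bin_width
  bin_width: 0.5        # HU per bin
glcm:
  distance: 1
  directions: 13        # unique 3D offsets, symmetric matrices
  aggregation: average_per_direction
glrlm:
  directions: 13
  aggregation: average_per_direction
glszm:
  connectivity: 26
gldm:
  alpha: 0
  distance: 1
ngtdm:
  distance: 1
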