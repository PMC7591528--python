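# Per-biome PT-JPL parameter look-up table.
# k1, k2, beta are biome-calibrated; b1, b2, k_rn carry canonical PT-JPL
# defaults; t_opt null = derive per pixel as Ta at max(LAI * Ta * fAPAR).
forest:
  b1: 1.0
  b2: 1.0
  k1: 0.57
  k2: 0.81
  t_opt: null
  beta: 1.28
  k_rn: 0.6
shrub:
  b1: 1.0
  b2: 1.0
  k1: 0.56
  k2: 0.91
  t_opt: null
  beta: 1.17
  k_rn: 0.6
crop:
  b1: 1.0
  b2: 1.0
  k1: 0.59
  k2: 0.84
  t_opt: null
  beta: 1.43
  k_rn: 0.6
grass:
  b1: 1.0
  b2: 1.0
  k1: 0.59
  k2: 0.80
  t_opt: null
  beta: 0.80
  k_rn: 0.6
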