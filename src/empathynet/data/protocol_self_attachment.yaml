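name: self_attachment
amplitude: 90.0
perturb_fraction: 0.1
levels:
  L: 0.05
  M: 0.1
  H: 0.15
mpfc_pool_sampling:
  close: band_uniform
  distant: band_uniform
mpfc_band_fraction:
  close: 0.45
  distant: 0.75
phases:
- index: 1
  t_start: 0
  t_end: 10000
  mpfc_target_mode: close
  rules:
    BLMA_neg:
      kind: band
      lo: M
      hi: H
    AI:
      kind: band
      lo: M
      hi: H
    PI:
      kind: band
      lo: M
      hi: H
    aMCC:
      kind: band
      lo: L
      hi: M
    mPFC:
      kind: 'off'
    mOFC:
      kind: band
      lo: L
      hi: M
- index: 2
  t_start: 10000
  t_end: 20000
  mpfc_target_mode: close
  rules:
    BLMA_neg:
      kind: band
      lo: M
      hi: H
    AI:
      kind: ramp
      lo: H
      hi: L
    PI:
      kind: ramp
      lo: H
      hi: L
    aMCC:
      kind: ramp
      lo: L
      hi: H
    mPFC:
      kind: ramp
      lo: L
      hi: H
    mOFC:
      kind: band
      lo: L
      hi: M
- index: 3
  t_start: 20000
  t_end: 30000
  mpfc_target_mode: close
  rules:
    BLMA_neg:
      kind: band
      lo: M
      hi: H
    AI:
      kind: band
      lo: L
      hi: M
    PI:
      kind: band
      lo: L
      hi: M
    aMCC:
      kind: band
      lo: M
      hi: H
    mPFC:
      kind: band
      lo: M
      hi: H
    mOFC:
      kind: ramp
      lo: L
      hi: H
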