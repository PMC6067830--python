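name: empathy
current_gain: 0.036
regions:
  BLMA_neg:
    n_exc: 160
    n_inh: 40
    type_exc: RS
    type_inh: FS
    valence: negative
  BLMA_pos:
    n_exc: 160
    n_inh: 40
    type_exc: RS
    type_inh: FS
    valence: positive
  BLMA_i:
    n_exc: 0
    n_inh: 100
    type_inh: FS
    valence: interneuron
  AI:
    n_exc: 200
    n_inh: 50
    type_exc: RS
    type_inh: FS
  PI:
    n_exc: 200
    n_inh: 50
    type_exc: RS
    type_inh: FS
  aMCC:
    n_exc: 200
    n_inh: 50
    type_exc: RS
    type_inh: FS
  mPFC:
    n_exc: 2000
    n_inh: 500
    type_exc: RS
    type_inh: FS
  mPOA:
    n_exc: 160
    n_inh: 40
    type_exc: RS
    type_inh: FS
  VTA:
    n_exc: 160
    n_inh: 40
    type_exc: IB
    type_inh: FS
    dopaminergic: true
  NAc:
    n_exc: 0
    n_inh: 200
    type_inh: RS
  VP:
    n_exc: 0
    n_inh: 200
    type_inh: FS
gradient:
  close_other:
  - 7
  - 0.0025
  distant_other:
  - 14
  - 0.035
  axis_orientation: ventral_at_high_index
projections:
- source: BLMA_neg.exc
  target: AI
  sign: excitatory
  p: 0.002
  w: 20.0
- source: AI.exc
  target: aMCC
  sign: excitatory
  p: 0.005
  w: 24.0
- source: aMCC.exc
  target: AI
  sign: excitatory
  p: 0.0006
  w: 24.0
- source: AI.exc
  target: mPFC
  sign: excitatory
  p: 0.004
  w: 24.0
  sampling: mpfc_gradient_distant
- source: mPFC.exc
  target: mPOA
  sign: excitatory
  p: 0.008
  w: 10.0
  sampling: mpfc_gradient
- source: mPFC.exc
  target: BLMA_pos
  sign: excitatory
  p: 0.0085
  w: 12.0
  sampling: mpfc_gradient
- source: mPOA.exc
  target: VTA
  sign: excitatory
  p: 0.01
  w: 20.0
- source: VTA.exc
  target: NAc
  sign: inhibitory
  p: 0.5
  w: 1.5
- source: NAc.inh
  target: VP
  sign: inhibitory
  p: 0.7
  w: 2.2
- source: BLMA_pos.exc
  target: VP
  sign: excitatory
  p: 0.006
  w: 22.0
- source: BLMA_pos.exc
  target: NAc
  sign: excitatory
  p: 0.02
  w: 20.0
- source: BLMA_pos.exc
  target: BLMA_i
  sign: excitatory
  p: 0.0035
  w: 20.0
- source: BLMA_i.inh
  target: BLMA_neg
  sign: inhibitory
  p: 0.5
  w: 1.5
- source: BLMA_neg.exc
  target: BLMA_neg.inh
  sign: excitatory
  p: 0.2
  w: 14.0
  intra: true
- source: BLMA_neg.inh
  target: BLMA_neg.exc
  sign: inhibitory
  p: 0.6
  w: 1.5
  intra: true
- source: BLMA_neg.inh
  target: BLMA_neg.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: BLMA_pos.exc
  target: BLMA_pos.exc
  sign: excitatory
  p: 0.08
  w: 9.7
  intra: true
- source: BLMA_pos.exc
  target: BLMA_pos.inh
  sign: excitatory
  p: 0.08
  w: 14.0
  intra: true
- source: BLMA_pos.inh
  target: BLMA_pos.exc
  sign: inhibitory
  p: 0.6
  w: 1.5
  intra: true
- source: BLMA_pos.inh
  target: BLMA_pos.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: AI.exc
  target: AI.inh
  sign: excitatory
  p: 0.17
  w: 14.0
  intra: true
- source: AI.inh
  target: AI.exc
  sign: inhibitory
  p: 0.6
  w: 3.0
  intra: true
- source: AI.inh
  target: AI.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: PI.exc
  target: PI.inh
  sign: excitatory
  p: 0.3
  w: 14.0
  intra: true
- source: PI.inh
  target: PI.exc
  sign: inhibitory
  p: 0.6
  w: 1.5
  intra: true
- source: PI.inh
  target: PI.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: aMCC.exc
  target: aMCC.inh
  sign: excitatory
  p: 0.125
  w: 14.0
  intra: true
- source: aMCC.inh
  target: aMCC.exc
  sign: inhibitory
  p: 1.0
  w: 2.5
  intra: true
- source: aMCC.inh
  target: aMCC.inh
  sign: inhibitory
  p: 0.6
  w: 3.0
  intra: true
- source: mPFC.exc
  target: mPFC.exc
  sign: excitatory
  p: 0.025
  w: 3.15
  intra: true
- source: mPFC.exc
  target: mPFC.inh
  sign: excitatory
  p: 0.026
  w: 14.0
  intra: true
- source: mPFC.inh
  target: mPFC.exc
  sign: inhibitory
  p: 0.1
  w: 1.5
  intra: true
- source: mPFC.inh
  target: mPFC.inh
  sign: inhibitory
  p: 0.1
  w: 2.0
  intra: true
- source: mPOA.exc
  target: mPOA.inh
  sign: excitatory
  p: 0.1
  w: 14.0
  intra: true
- source: mPOA.inh
  target: mPOA.exc
  sign: inhibitory
  p: 0.6
  w: 1.5
  intra: true
- source: mPOA.inh
  target: mPOA.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: VTA.exc
  target: VTA.inh
  sign: excitatory
  p: 0.1
  w: 14.0
  intra: true
- source: VTA.inh
  target: VTA.exc
  sign: inhibitory
  p: 0.6
  w: 1.5
  intra: true
- source: VTA.inh
  target: VTA.inh
  sign: inhibitory
  p: 0.6
  w: 2.0
  intra: true
- source: NAc.inh
  target: NAc.inh
  sign: inhibitory
  p: 0.6
  w: 2.5
  intra: true
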