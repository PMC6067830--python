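required:
- - BLMA_neg
  - AI
  - excitatory
- - AI
  - aMCC
  - excitatory
- - aMCC
  - AI
  - excitatory
- - AI
  - mPFC
  - excitatory
- - mPFC
  - mPOA
  - excitatory
- - mPFC
  - BLMA_pos
  - excitatory
- - mPOA
  - VTA
  - excitatory
- - VTA
  - NAc
  - inhibitory
- - NAc
  - VP
  - inhibitory
- - BLMA_pos
  - VP
  - excitatory
- - BLMA_pos
  - NAc
  - excitatory
- - BLMA_pos
  - BLMA_i
  - excitatory
- - BLMA_i
  - BLMA_neg
  - inhibitory
optional:
- - PI
  - AI
  - excitatory
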