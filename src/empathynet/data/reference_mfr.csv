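model,region,subpop,time_s,mfr_hz
empathy,AI,exc,10.0,1.08
empathy,AI,inh,10.0,8.80
empathy,AI,exc,20.0,0.22
empathy,AI,inh,20.0,1.92
empathy,AI,exc,30.0,0.45
empathy,AI,inh,30.0,4.33
empathy,PI,exc,10.0,1.09
empathy,PI,inh,10.0,10.55
empathy,PI,exc,20.0,0.06
empathy,PI,inh,20.0,1.97
empathy,PI,exc,30.0,0.34
empathy,PI,inh,30.0,3.69
empathy,aMCC,exc,10.0,1.09
empathy,aMCC,inh,10.0,5.97
empathy,aMCC,exc,20.0,0.93
empathy,aMCC,inh,20.0,4.79
empathy,aMCC,exc,30.0,1.05
empathy,aMCC,inh,30.0,5.61
empathy,mPFC,exc,10.0,0.84
empathy,mPFC,inh,10.0,5.25
empathy,mPFC,exc,20.0,1.30
empathy,mPFC,inh,20.0,8.53
empathy,mPFC,exc,30.0,1.26
empathy,mPFC,inh,30.0,8.82
empathy,BLMA_neg,exc,10.0,0.92
empathy,BLMA_neg,exc,20.0,0.75
empathy,BLMA_neg,exc,30.0,0.72
empathy,BLMA_pos,exc,20.0,0.21
empathy,BLMA_pos,exc,30.0,6.75
empathy,VP,inh,30.0,2.44
self_attachment,AI,exc,10.0,1.01
self_attachment,AI,inh,10.0,8.01
self_attachment,AI,exc,20.0,0.10
self_attachment,AI,inh,20.0,1.31
self_attachment,AI,exc,30.0,0.32
self_attachment,AI,inh,30.0,4.97
self_attachment,PI,exc,10.0,1.05
self_attachment,PI,inh,10.0,10.09
self_attachment,PI,exc,20.0,0.01
self_attachment,PI,inh,20.0,2.52
self_attachment,aMCC,exc,10.0,1.09
self_attachment,aMCC,inh,10.0,5.06
self_attachment,aMCC,exc,20.0,1.11
self_attachment,aMCC,inh,20.0,6.23
self_attachment,aMCC,exc,30.0,1.01
self_attachment,aMCC,inh,30.0,4.97
self_attachment,mPFC,exc,10.0,0.73
self_attachment,mPFC,inh,10.0,4.82
self_attachment,mPFC,exc,20.0,1.41
self_attachment,mPFC,inh,20.0,10.07
self_attachment,mOFC,exc,30.0,1.80
self_attachment,mOFC,inh,30.0,12.17
self_attachment,BLMA_neg,exc,10.0,0.91
self_attachment,BLMA_neg,exc,20.0,0.61
self_attachment,BLMA_neg,exc,30.0,0.51
self_attachment,BLMA_pos,exc,20.0,7.13
self_attachment,BLMA_pos,exc,30.0,9.05
self_attachment,BLMA_i,inh,20.0,3.31
self_attachment,BLMA_i,inh,30.0,13.62
self_attachment,VP,inh,10.0,0.00
self_attachment,VP,inh,20.0,2.56
self_attachment,VP,inh,30.0,3.56
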