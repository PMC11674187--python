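# Mean fractional inhibition at a single test concentration, with
# time-matched vehicle-control rundown, for the single-point IC50 estimator.
channel,concentration_uM,inhibition_drug,inhibition_control,n_h
INa_peak,200,0.6953,0.0,1
IKs,200,0.3668,0.2366,1
IKr,200,0.1097,0.041,1
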