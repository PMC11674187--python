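# Use-dependent-block analysis of four experiments on hNav1.5-expressing
# HEK293 cells (5 depolarizing pulses at -10 mV, t_d = 10 ms, interpulse
# intervals at -120 mV growing from 5 to 50 ms across sweeps).
# tau_i: control inactivation; tau_r: control recovery; tau_i_ob: decay with
# drug (inactivation + open block); tau_ib_est: estimated inactivated-state
# block/unblock time constant. All in ms.
exp,tau_i_ms,tau_r_ms,tau_i_ob_ms,tau_ib_est_ms
23o10,2.36,3.31,2.23,4.08
a3o10,2.62,3.76,3.04,3.83
b3o10,2.93,5.13,2.94,4.94
c3o10,1.95,3.04,1.73,3.25
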