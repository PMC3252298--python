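# Classical squid-axon sodium and delayed-rectifier potassium channel kinetics
# (Hodgkin & Huxley 1952, J Physiol 117:500-544), in the modern convention with
# the resting potential near -65 mV.  Rates are declared in 1/ms and voltages
# in mV and converted to SI on load.
#
#   alpha_m = 0.1 (V+40) / (1 - exp(-(V+40)/10))     beta_m = 4 exp(-(V+65)/18)
#   alpha_h = 0.07 exp(-(V+65)/20)                   beta_h = 1 / (1 + exp(-(V+35)/10))
#   alpha_n = 0.01 (V+55) / (1 - exp(-(V+55)/10))    beta_n = 0.125 exp(-(V+65)/80)
version: 1
name: hh_squid_channels
units:
  rate: 1/ms
  voltage: mV
channels:
  na:
    gates:
      - name: m
        power: 3
        alpha: {family: exp_linear, A: 0.1, V0: -40.0, K: 10.0}
        beta: {family: exponential, A: 4.0, V0: -65.0, K: -18.0}
      - name: h
        power: 1
        alpha: {family: exponential, A: 0.07, V0: -65.0, K: -20.0}
        beta: {family: sigmoid, A: 1.0, V0: -35.0, K: 10.0}
  k:
    gates:
      - name: n
        power: 4
        alpha: {family: exp_linear, A: 0.01, V0: -55.0, K: 10.0}
        beta: {family: exponential, A: 0.125, V0: -65.0, K: -80.0}
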