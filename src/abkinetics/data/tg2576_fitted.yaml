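# Fitted vicious-cycle parameter set for soluble Abeta42 in Tg2576 mouse brain.
# k2, A_init and X_init were held fixed during the fit.
V1: 1.36e+6      # pg mg^-1 mo^-1
K1: 10.7         # dimensionless
k2: 450.0        # mo^-1
V1p: 0.998       # mo^-1
K1p: 134.2       # pg/mg
k2p: 0.00168     # mo^-1
hill_n: 2
A_init: 34.0     # pg/mg at t = 1 mo
X_init: 1.0
basal: 0.0
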