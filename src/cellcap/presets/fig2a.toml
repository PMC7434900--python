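name = "fig2a"
description = "Adder with exponential growth: capacity increases monotonically with newborn size."

[growth_law]
kind = "exponential"
alpha = 0.020833333333333332

[division_rule]
a = 1.0
vbar = 30.0
tmin = 20.0

[experiment]
t_f = 72.0
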