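name = "fig2c"
description = "Adder with a strictly decreasing growth rate: capacity decreases with newborn size."

[growth_law]
kind = "reciprocal"
alpha = 0.020833333333333332
v_th = 30.0

[division_rule]
a = 1.0
vbar = 30.0
tmin = 20.0

[experiment]
t_f = 72.0
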