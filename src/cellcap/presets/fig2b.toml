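name = "fig2b"
description = "Adder with a saturating growth rate: capacity still increases with newborn size."

[growth_law]
kind = "saturating"
alpha = 0.020833333333333332
v_th = 25.0

[division_rule]
a = 1.0
vbar = 30.0
tmin = 20.0

[experiment]
t_f = 72.0
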