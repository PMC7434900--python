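name = "fig3c"
description = "Adder-timer mixture (a=1.5) with a saturating growth rate: bell-shaped capacity from a monotone growth law."

[growth_law]
kind = "saturating"
alpha = 0.020833333333333332
v_th = 25.0

[division_rule]
a = 1.5
vbar = 30.0
tmin = 20.0

[experiment]
t_f = 72.0
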