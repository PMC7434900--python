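name = "fig3b"
description = "Sizer-adder mixture (a=0.6) with a non-monotone growth rate: bell shape, then a late rise as newborns approach the size where division size falls below birth size."

[growth_law]
kind = "power_saturating"
alpha = 0.020833333333333332
v_th = 20.0
k = 3.0

[division_rule]
a = 0.6
vbar = 30.0
tmin = 20.0

[experiment]
t_f = 72.0
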