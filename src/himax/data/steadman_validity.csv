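# Best-effort boundary of the Steadman (1979) model's designed range.
# Inside the range: RH <= rh_max interpolated at the given temperature.
# Mild/cool conditions are always inside; only extreme hot-humid
# combinations (where the thermoregulation model becomes unphysical)
# fall outside.  Editable: swap in an alternative boundary if needed.
temp_f,rh_max_pct
68,100
85,100
90,100
95,80
100,62
105,48
110,38
115,30
120,24
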