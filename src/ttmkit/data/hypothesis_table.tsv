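parameter	Co_same	Co_plus_Ca	Co_plus_Myosin	Co_plus_cAMP	Co_minus_Ca	Co_minus_Tox
AP_amplitude	same	same	same	same	down	down
AP_t_rise	same	down	same	down	not_down	up
AP_t_APD	same	not_same	same	down	down	not_up
AP_triangulation	same	down	same	down	down	up
Ca_amplitude	same	up	same	up	down	down
Ca_t_to_peak	same	not_down	not_up	down	down	not_up
Ca_t_decay	same	not_down	not_up	down	down	not_up
Co_amplitude	same	up	up	up	down	down
Co_t_contraction	same	not_down	up	down	down	not_up
Co_t_relaxation	same	not_down	not_down	down	down	not_up
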