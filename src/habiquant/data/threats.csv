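name,codes,d_rmax_km,weight,decay
Industrial and mining land,16,8.00,0.70,exponential
Arable land,1;2,3.50,0.60,linear
Urban land,14,5.00,0.90,exponential
Rural settlements,15,4.00,0.60,exponential
Saline-alkali land,18,2.50,0.30,linear
Bare ground,20;21,2.50,0.30,exponential
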