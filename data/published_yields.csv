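energy_mev,environment,dose_rate_class,ssb_yield,ssb_err,dsb_yield,dsb_err,dose_unit
100,dry,conventional,69.81,8.72,3.66,0.43,kGy
150,dry,conventional,80.30,3.06,3.71,0.11,kGy
200,dry,conventional,50.27,4.19,3.83,0.45,kGy
100,wet,conventional,15.42,0.86,0.35,0.02,Gy
150,wet,conventional,17.63,0.57,0.35,0.03,Gy
200,wet,conventional,20.19,0.56,0.38,0.02,Gy
100,wet,flash,20.31,1.20,0.37,0.03,Gy
150,wet,flash,18.74,0.52,0.37,0.04,Gy
200,wet,flash,21.22,0.38,0.38,0.02,Gy
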