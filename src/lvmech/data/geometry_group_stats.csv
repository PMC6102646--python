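group,phase,R_b_mean,R_b_sd,L_mean,L_sd,Z_mean,Z_sd,H_mean,H_sd,e_mean,e_sd,psi0_deg_mean,psi0_deg_sd
N,EoD,33,3,8.4,0.9,48,4,7.6,2.1,0.76,0.07,-66,14
N,BoD,29,2,13,2,50,6,8.7,2.9,0.69,0.09,-55,12
HYP,EoD,35,4,10,2,49,10,8.9,4.0,0.74,0.10,-62,16
HYP,BoD,32,5,15,3,49,10,8.8,3.2,0.67,0.19,-54,16
HF-NI,EoD,41,3,9.4,0.9,56,6,7.3,2.4,0.77,0.08,-74,6
HF-NI,BoD,39,4,11,1,56,6.2,7.7,2.5,0.81,0.12,-69,11.0
HF-I,EoD,41,5,8.9,0.8,53,5,6.7,2.3,0.71,0.07,-69,7
HF-I,BoD,39,5,11,2,54,5,6.9,2.2,0.76,0.13,-65,11
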