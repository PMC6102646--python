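id,group,phase,R_b,L,Z,H,e,psi0_deg
N-02,N,EoD,33,8.1,49,8.4,0.71,-74
N-02,N,BoD,29,11,49,7.9,0.64,-77
N-03,N,EoD,33,7.5,46,5.4,0.75,-79
N-03,N,BoD,30,13,45,5.6,0.78,-56
N-05,N,EoD,30,8.1,43,6.9,0.7,-61
N-05,N,BoD,26,12,44,6.3,0.71,-48
N-06,N,EoD,32,7.3,44,5.6,0.87,-69
N-06,N,BoD,29,11,44,5.2,0.8,-58
N-07,N,EoD,34,9.3,54,11,0.7,-60
N-07,N,BoD,30,12,55,12,0.6,-44
N-09,N,EoD,38,8.2,47,9.1,0.72,-78
N-09,N,BoD,32,12,51,13,0.54,-66
N-10,N,EoD,33,10,56,5.4,0.73,-80
N-10,N,BoD,30,17,63,11,0.69,-56
N-11,N,EoD,34,8.7,48,6.6,0.8,-50
N-11,N,BoD,31,14,49,7.2,0.68,-52
N-40,N,EoD,29,8.1,49,9.7,0.87,-40
N-40,N,BoD,26,11,50,10,0.81,-34
HYP-01,HYP,EoD,32,7.1,39,5.3,0.64,-79
HYP-01,HYP,BoD,27,12,40,6.4,0.46,-70
HYP-03,HYP,EoD,34,9.5,42,6.1,0.6,-72
HYP-03,HYP,BoD,33,18,47,8.0,0.55,-43
HYP-06,HYP,EoD,34,9.3,38,6.4,0.75,-76
HYP-06,HYP,BoD,29,12,37,5.6,0.68,-76
HYP-07,HYP,EoD,39,12,53,7.9,0.96,-50
HYP-07,HYP,BoD,35,18,57,7.3,0.89,-47
HYP-08,HYP,EoD,44,14,65,11,0.82,-61
HYP-08,HYP,BoD,41,20,64,9.6,0.93,-42
HYP-09,HYP,EoD,35,7.9,54,7.5,0.82,-76
HYP-09,HYP,BoD,32,13,45,9.6,0.7,-68
HYP-10,HYP,EoD,40,9.0,46,5.3,0.69,-61
HYP-10,HYP,BoD,36,13,45,5.1,0.56,-56
HYP-11,HYP,EoD,31,9.7,37,6.6,0.83,-79
HYP-11,HYP,BoD,29,14,33,5.1,0.98,-79
HYP-12,HYP,EoD,28,7.1,49,8.3,0.7,-66
HYP-12,HYP,BoD,24,12,52,11,0.43,-49
HYP-37,HYP,EoD,36,11,51,13,0.67,-33
HYP-37,HYP,BoD,32,17,54,12,0.55,-28
HYP-38,HYP,EoD,34,13,68,19,0.66,-45
HYP-38,HYP,BoD,30,17,64,16,0.52,-53
HYP-40,HYP,EoD,32,13,50,10,0.8,-41
HYP-40,HYP,BoD,30,16,50,10,0.85,-39
HF-NI-03,HF-NI,EoD,46,11,52,6.3,0.88,-78
HF-NI-03,HF-NI,BoD,44,13,54,6.5,0.96,-60
HF-NI-04,HF-NI,EoD,42,8.4,49,5.9,0.71,-73
HF-NI-04,HF-NI,BoD,40,13,49,5.2,0.69,-58
HF-NI-07,HF-NI,EoD,39,8.8,64,12,0.69,-68
HF-NI-07,HF-NI,BoD,37,11,62,10,0.75,-73
HF-NI-11,HF-NI,EoD,44,9.7,59,5.7,0.69,-79
HF-NI-11,HF-NI,BoD,42,10,56,5.2,0.67,-77
HF-NI-12,HF-NI,EoD,47,8.7,62,7,0.79,-78
HF-NI-12,HF-NI,BoD,44,11,61,6.7,0.87,-74
HF-NI-13,HF-NI,EoD,41,9.7,62,8.4,0.9,-80
HF-NI-13,HF-NI,BoD,40,12,64,9.5,0.88,-79
HF-NI-14,HF-NI,EoD,40,11,53,7.6,0.79,-68
HF-NI-14,HF-NI,BoD,37,12,55,10,0.82,-62
HF-NI-15,HF-NI,EoD,36,9.3,56,12,0.81,-64
HF-NI-15,HF-NI,BoD,32,9.7,57,12,0.92,-58
HF-NI-31,HF-NI,EoD,40,9.4,49,5.8,0.84,-78
HF-NI-31,HF-NI,BoD,35,11,49,5.2,0.98,-79
HF-NI-33,HF-NI,EoD,37,9.2,57,6.7,0.7,-80
HF-NI-33,HF-NI,BoD,34,12,55,6.2,0.64,-77
HF-NI-34,HF-NI,EoD,40,9.4,58,5.1,0.71,-71
HF-NI-34,HF-NI,BoD,39,13,63,10,0.72,-49
HF-NI-36,HF-NI,EoD,43,8.5,45,5.2,0.79,-77
HF-NI-36,HF-NI,BoD,41,9.3,44,5.4,0.77,-79
HF-I-01,HF-I,EoD,38,8.3,54,5.1,0.84,-64
HF-I-01,HF-I,BoD,36,9.4,54,5.1,0.95,-67
HF-I-02,HF-I,EoD,44,9.5,52,5.7,0.65,-75
HF-I-02,HF-I,BoD,40,10,53,5.9,0.65,-75
HF-I-04,HF-I,EoD,41,8.8,50,5.7,0.66,-63
HF-I-04,HF-I,BoD,40,11,51,5.3,0.66,-55
HF-I-05,HF-I,EoD,41,9.4,48,8.9,0.68,-67
HF-I-05,HF-I,BoD,38,11,54,11,0.83,-48
HF-I-06,HF-I,EoD,39,8.5,54,5.3,0.7,-77
HF-I-06,HF-I,BoD,38,11,57,5.3,0.84,-75
HF-I-07,HF-I,EoD,38,10,42,6.8,0.57,-71
HF-I-07,HF-I,BoD,37,14,43,8.1,0.46,-70
HF-I-08,HF-I,EoD,42,9.4,54,5.4,0.77,-59
HF-I-08,HF-I,BoD,41,11,54,5.2,0.77,-57
HF-I-09,HF-I,EoD,51,10,65,5.4,0.74,-72
HF-I-09,HF-I,BoD,50,11,64,5.2,0.73,-69
HF-I-10,HF-I,EoD,49,9.2,53,5.1,0.74,-73
HF-I-10,HF-I,BoD,47,10,58,9.0,0.83,-79
HF-I-11,HF-I,EoD,40,7.2,55,5.9,0.68,-59
HF-I-11,HF-I,BoD,39,9.4,54,5.0,0.81,-61
HF-I-12,HF-I,EoD,36,8.4,54,7.6,0.69,-67
HF-I-12,HF-I,BoD,34,15,56,7.2,0.74,-50
HF-I-40,HF-I,EoD,33,8.2,54,13,0.76,-80
HF-I-40,HF-I,BoD,31,12,51,10,0.88,-78
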