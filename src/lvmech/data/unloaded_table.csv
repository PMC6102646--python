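id,target,R_b,L,Z,H,e,psi0_deg
N-02,lff10,30,9.3,50,9.1,0.65,-68
N-02,lff15,30,10,51,9.8,0.65,-60
N-03,lff10,30,8.4,47,6,0.70,-74
N-03,lff15,29,9.4,47,6.5,0.71,-66
N-05,lff10,28,9.3,45,7.6,0.65,-53
N-05,lff15,28,10,46,8.1,0.65,-45
N-06,lff10,29,8.4,45,6,0.86,-60
N-06,lff15,29,9.3,45,6.6,0.89,-53
N-07,lff10,32,11,56,12,0.63,-53
N-07,lff15,32,12,58,13,0.63,-45
N-09,lff10,35,9.6,54,12,0.70,-53
N-09,lff15,34,11,55,13,0.70,-45
N-10,lff10,30,11,58,5.6,0.69,-75
N-10,lff15,30,12,58,6.1,0.71,-68
N-11,lff10,32,10,49,7.4,0.76,-43
N-11,lff15,32,11,50,7.9,0.78,-35
N-40,lff10,28,9.5,51,10,0.83,-33
N-40,lff15,28,10,52,11,0.84,-27
HYP-01,lff10,30,7.9,39,6.2,0.57,-73
HYP-01,lff15,30,8.9,39,6.8,0.56,-64
HYP-03,lff10,32,11,43,6.9,0.54,-64
HYP-03,lff15,32,12,43,7.6,0.54,-55
HYP-06,lff10,32,11,38,7.4,0.73,-64
HYP-06,lff15,32,12,39,8.1,0.75,-57
HYP-07,lff10,37,14,56,8.8,1.00,-37
HYP-07,lff15,36,15,57,9.3,1.00,-31
HYP-08,lff10,41,16,68,11,0.82,-51
HYP-08,lff15,41,17,70,12,0.84,-44
HYP-09,lff10,33,9,55,8,0.80,-70
HYP-09,lff15,32,9.7,55,8.7,0.81,-63
HYP-10,lff10,36,9.5,46,6.2,0.58,-75
HYP-10,lff15,35,10,46,6.9,0.57,-66
HYP-11,lff10,29,12,38,7.3,0.83,-67
HYP-11,lff15,29,13,39,7.9,0.86,-60
HYP-12,lff10,26,8.1,51,8.7,0.65,-60
HYP-12,lff15,26,9.1,51,9.4,0.65,-53
HYP-37,lff10,31,11,53,13,0.55,-48
HYP-37,lff15,32,12,54,14,0.55,-40
HYP-38,lff10,32,14,71,17,0.61,-38
HYP-38,lff15,33,15,72,17,0.60,-32
HYP-40,lff10,31,15,53,11,0.78,-31
HYP-40,lff15,31,16,54,12,0.80,-24
HF-NI-03,lff10,43,12,52,7.2,0.89,-60
HF-NI-03,lff15,42,13,53,8,0.91,-53
HF-NI-04,lff10,39,9.3,49,6.9,0.66,-73
HF-NI-04,lff15,38,10,49,7.7,0.66,-64
HF-NI-07,lff10,36,9.4,66,14,0.59,-61
HF-NI-07,lff15,35,10,67,14,0.58,-54
HF-NI-11,lff10,40,11,60,6.4,0.63,-76
HF-NI-11,lff15,39,12,60,7,0.63,-68
HF-NI-12,lff10,43,9.6,63,8.4,0.77,-73
HF-NI-12,lff15,41,10,63,9.2,0.77,-67
HF-NI-13,lff10,38,11,63,9,0.89,-74
HF-NI-13,lff15,37,11,63,9.6,0.90,-68
HF-NI-14,lff10,37,12,54,8.3,0.77,-58
HF-NI-14,lff15,36,14,55,9.1,0.79,-50
HF-NI-15,lff10,34,11,60,13,0.85,-48
HF-NI-15,lff15,34,12,61,14,0.86,-41
HF-NI-31,lff10,37,11,50,6.6,0.84,-69
HF-NI-31,lff15,36,12,50,7.2,0.86,-62
HF-NI-33,lff10,34,10,58,7.3,0.64,-76
HF-NI-33,lff15,33,11,58,8,0.64,-69
HF-NI-34,lff10,37,10,59,5.6,0.65,-67
HF-NI-34,lff15,36,11,60,6.3,0.65,-59
HF-NI-36,lff10,40,9.4,45,5.9,0.82,-65
HF-NI-36,lff15,39,10,46,6.6,0.83,-58
HF-I-01,lff10,35,9.4,55,5.5,0.82,-57
HF-I-01,lff15,34,10,56,6,0.84,-50
HF-I-02,lff10,41,11,53,6.6,0.59,-70
HF-I-02,lff15,39,12,53,7.3,0.58,-61
HF-I-04,lff10,38,9.8,50,6.6,0.59,-57
HF-I-04,lff15,38,11,51,7.3,0.58,-49
HF-I-05,lff10,39,11,49,10,0.61,-59
HF-I-05,lff15,38,12,50,11,0.60,-50
HF-I-06,lff10,36,9.4,55,5.9,0.64,-74
HF-I-06,lff15,35,10,55,6.5,0.64,-66
HF-I-07,lff10,36,12,42,7.8,0.50,-62
HF-I-07,lff15,36,14,43,8.6,0.50,-53
HF-I-08,lff10,39,10,55,5.6,0.74,-58
HF-I-08,lff15,38,12,55,6.3,0.75,-50
HF-I-09,lff10,47,10,74,13,0.73,-68
HF-I-09,lff15,45,12,74,14,0.73,-62
HF-I-10,lff10,46,10,52,5.9,0.70,-66
HF-I-10,lff15,44,11,53,6.7,0.70,-58
HF-I-11,lff10,36,7.1,54,5.7,0.60,-67
HF-I-11,lff15,35,7.8,54,6.4,0.59,-59
HF-I-12,lff10,33,9.4,55,8.3,0.63,-62
HF-I-12,lff15,33,10,56,9,0.63,-54
HF-I-40,lff10,31,9.6,55,13,0.71,-73
HF-I-40,lff15,30,10,56,14,0.70,-65
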