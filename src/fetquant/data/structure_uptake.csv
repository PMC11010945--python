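structure,timepoint,n,mean,median,min,max,lower_q,upper_q,sd
plexus,10,23,1.12,1.07,0.48,1.86,0.91,1.28,0.31
thalamus_max,10,23,1.04,0.97,0.46,2.15,0.80,1.19,0.37
thalamus,10,23,0.77,0.77,0.35,1.76,0.60,0.86,0.27
brain,10,23,0.60,0.60,0.33,1.23,0.47,0.69,0.20
brain_max,10,23,1.09,1.05,0.47,1.88,0.92,1.22,0.32
artery,10,23,0.78,0.77,0.42,1.17,0.64,0.90,0.19
sinus,10,23,1.88,1.92,0.71,3.25,1.45,2.08,0.55
sinus,60,23,1.46,1.45,0.82,2.23,1.07,1.83,0.41
plexus,60,23,0.98,0.91,0.56,1.92,0.76,1.13,0.31
thalamus_max,60,22,1.17,1.10,0.63,2.30,0.90,1.39,0.40
thalamus,60,23,0.90,0.88,0.43,1.86,0.72,1.05,0.30
brain,60,23,0.73,0.74,0.44,1.31,0.51,0.88,0.23
brain_max,60,23,1.20,1.17,0.60,2.03,0.83,1.48,0.37
artery,60,23,0.85,0.82,0.45,1.31,0.60,1.08,0.26
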