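histology,timepoint,n,mean,median,min,max,lower_q,upper_q,sd
astrogliosis,10,52,1.12,1.04,0.34,2.98,0.76,1.47,0.54
astrogliosis,60,53,1.40,1.21,0.43,2.61,1.02,1.83,0.57
G2,10,45,1.35,1.23,0.55,4.02,1.01,1.54,0.60
G2,60,45,1.60,1.47,0.79,3.07,1.05,1.77,0.62
G3,10,125,2.05,1.96,0.50,4.47,1.39,2.55,0.89
G3,60,125,2.27,2.18,0.53,5.86,1.47,2.75,0.99
G4,10,60,2.50,2.75,0.72,4.08,1.60,3.20,0.87
G4,60,60,2.60,2.56,1.15,5.86,1.72,2.87,1.17
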