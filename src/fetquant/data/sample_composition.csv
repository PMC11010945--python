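histology,overall,T1-GAD,PET,PET-,FLAIR
astrogliosis,54,4,9,3,38
G2,45,5,21,6,13
G3,125,55,51,2,17
G4,60,27,29,0,4
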