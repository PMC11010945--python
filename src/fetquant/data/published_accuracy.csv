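timepoint,feature,cutoff,sensitivity,specificity,ppv,npv,auc,ci_low,ci_high
10,tbr_brain,1.60,0.93,0.37,0.87,0.56,0.809,0.744,0.874
10,tbr_brain_max,1.60,0.57,0.87,0.95,0.31,0.796,0.730,0.862
10,tbr_plexus,1.00,0.87,0.65,0.92,0.53,0.868,0.820,0.917
10,tbr_plexus_roimean,1.00,0.95,0.58,0.90,0.71,0.869,0.814,0.923
10,tbr_thalamus,1.55,0.83,0.69,0.92,0.48,0.801,0.735,0.868
10,tbr_thalamus_max,1.40,0.74,0.69,0.91,0.38,0.742,0.668,0.817
10,tbr_artery,1.90,0.71,0.85,0.95,0.40,0.831,0.774,0.889
10,tbr_sinus,0.74,0.77,0.81,0.95,0.44,0.843,0.788,0.899
60,tbr_brain,1.60,0.91,0.36,0.86,0.48,0.797,0.738,0.856
60,tbr_brain_max,1.60,0.57,0.75,0.91,0.29,0.7621,0.698,0.827
60,tbr_plexus,1.20,0.94,0.40,0.87,0.60,0.845,0.790,0.900
60,tbr_plexus_roimean,1.20,0.91,0.38,0.86,0.51,0.828,0.773,0.883
60,tbr_thalamus,1.80,0.77,0.70,0.92,0.41,0.789,0.725,0.852
60,tbr_thalamus_max,1.10,0.88,0.51,0.88,0.50,0.752,0.680,0.823
60,tbr_artery,2.10,0.64,0.79,0.93,0.34,0.788,0.727,0.849
60,tbr_sinus,1.30,0.63,0.89,0.960,0.35,0.793,0.735,0.850
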