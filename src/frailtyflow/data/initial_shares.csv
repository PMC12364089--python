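cohort,band,state,percent
RCGP,50-64,Fit,46.8
RCGP,50-64,Mild,5.14
RCGP,50-64,Moderate,0.49
RCGP,50-64,Severe,0.048
RCGP,65-74,Fit,16.95
RCGP,65-74,Mild,6.27
RCGP,65-74,Moderate,1.08
RCGP,65-74,Severe,0.13
RCGP,75-84,Fit,7.82
RCGP,75-84,Mild,6.51
RCGP,75-84,Moderate,2.14
RCGP,75-84,Severe,0.45
RCGP,85+,Fit,1.93
RCGP,85+,Mild,2.53
RCGP,85+,Moderate,1.30
RCGP,85+,Severe,0.42
SAIL,50-64,Fit,43.16
SAIL,50-64,Mild,8.65
SAIL,50-64,Moderate,0.94
SAIL,50-64,Severe,0.08
SAIL,65-74,Fit,14.83
SAIL,65-74,Mild,8.15
SAIL,65-74,Moderate,1.66
SAIL,65-74,Severe,0.21
SAIL,75-84,Fit,6.49
SAIL,75-84,Mild,7.02
SAIL,75-84,Moderate,2.54
SAIL,75-84,Severe,0.54
SAIL,85+,Fit,1.49
SAIL,85+,Mild,2.45
SAIL,85+,Moderate,1.36
SAIL,85+,Severe,0.42
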