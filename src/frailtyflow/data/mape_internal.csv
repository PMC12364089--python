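band,state,variable,mape
50-64,Fit,Alive,0.45
50-64,Fit,Entering,1.96
50-64,Fit,Dying,5.35
50-64,Fit,Deregistration,5.77
50-64,Fit,Ageing,10.35
50-64,Mild,Alive,1.42
50-64,Mild,Entering,2.37
50-64,Mild,Dying,6.55
50-64,Mild,Deregistration,6.93
50-64,Mild,Ageing,11.53
50-64,Moderate,Alive,6.93
50-64,Moderate,Entering,5.57
50-64,Moderate,Dying,7.58
50-64,Moderate,Deregistration,7.94
50-64,Moderate,Ageing,14.91
50-64,Severe,Alive,7.77
50-64,Severe,Entering,15.84
50-64,Severe,Dying,4.00
50-64,Severe,Deregistration,10.22
50-64,Severe,Ageing,19.45
50-64,Fit,FrailtyTransition,24.04
50-64,Mild,FrailtyTransition,3.43
50-64,Moderate,FrailtyTransition,4.83
65-74,Fit,Alive,3.89
65-74,Fit,Entering,5.43
65-74,Fit,Dying,5.64
65-74,Fit,Deregistration,4.93
65-74,Fit,Ageing,8.03
65-74,Mild,Alive,2.91
65-74,Mild,Entering,6.18
65-74,Mild,Dying,7.39
65-74,Mild,Deregistration,7.24
65-74,Mild,Ageing,6.99
65-74,Moderate,Alive,3.44
65-74,Moderate,Entering,7.15
65-74,Moderate,Dying,5.75
65-74,Moderate,Deregistration,9.90
65-74,Moderate,Ageing,11.82
65-74,Severe,Alive,5.39
65-74,Severe,Entering,22.48
65-74,Severe,Dying,7.40
65-74,Severe,Deregistration,9.45
65-74,Severe,Ageing,9.55
65-74,Fit,FrailtyTransition,9.30
65-74,Mild,FrailtyTransition,7.83
65-74,Moderate,FrailtyTransition,10.49
75-84,Fit,Alive,3.75
75-84,Fit,Entering,4.39
75-84,Fit,Dying,8.16
75-84,Fit,Deregistration,1.83
75-84,Fit,Ageing,10.94
75-84,Mild,Alive,1.53
75-84,Mild,Entering,5.42
75-84,Mild,Dying,6.30
75-84,Mild,Deregistration,5.58
75-84,Mild,Ageing,9.07
75-84,Moderate,Alive,3.50
75-84,Moderate,Entering,4.43
75-84,Moderate,Dying,5.91
75-84,Moderate,Deregistration,6.52
75-84,Moderate,Ageing,4.35
75-84,Severe,Alive,3.99
75-84,Severe,Entering,11.02
75-84,Severe,Dying,4.47
75-84,Severe,Deregistration,7.62
75-84,Severe,Ageing,8.54
75-84,Fit,FrailtyTransition,14.46
75-84,Mild,FrailtyTransition,5.50
75-84,Moderate,FrailtyTransition,6.54
85+,Fit,Alive,4.70
85+,Fit,Entering,4.67
85+,Fit,Dying,5.49
85+,Fit,Deregistration,6.12
85+,Mild,Alive,2.43
85+,Mild,Entering,4.01
85+,Mild,Dying,3.22
85+,Mild,Deregistration,4.71
85+,Moderate,Alive,2.23
85+,Moderate,Entering,5.52
85+,Moderate,Dying,2.51
85+,Moderate,Deregistration,8.38
85+,Severe,Alive,10.44
85+,Severe,Entering,16.08
85+,Severe,Dying,5.26
85+,Severe,Deregistration,11.87
85+,Fit,FrailtyTransition,6.23
85+,Mild,FrailtyTransition,6.79
85+,Moderate,FrailtyTransition,5.29
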