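band,state,variable,mape
50-64,Fit,Alive,2.09
50-64,Fit,Entering,5.05
50-64,Fit,Dying,9.48
50-64,Fit,Deregistration,4.77
50-64,Fit,Ageing,8.17
50-64,Mild,Alive,1.41
50-64,Mild,Entering,5.64
50-64,Mild,Dying,8.36
50-64,Mild,Deregistration,7.38
50-64,Mild,Ageing,12.3
50-64,Moderate,Alive,6.45
50-64,Moderate,Entering,8.35
50-64,Moderate,Dying,5.37
50-64,Moderate,Deregistration,11.73
50-64,Moderate,Ageing,10.26
50-64,Severe,Alive,6.73
50-64,Severe,Entering,18.86
50-64,Severe,Dying,5.12
50-64,Severe,Deregistration,10.92
50-64,Severe,Ageing,21.38
50-64,Fit,FrailtyTransition,3.05
50-64,Mild,FrailtyTransition,4.94
50-64,Moderate,FrailtyTransition,3.85
65-74,Fit,Alive,2.41
65-74,Fit,Entering,6.99
65-74,Fit,Dying,9.69
65-74,Fit,Deregistration,10.95
65-74,Fit,Ageing,6.08
65-74,Mild,Alive,7.10
65-74,Mild,Entering,25.24
65-74,Mild,Dying,9.84
65-74,Mild,Deregistration,7.26
65-74,Mild,Ageing,9.21
65-74,Moderate,Alive,5.58
65-74,Moderate,Entering,28.12
65-74,Moderate,Dying,4.01
65-74,Moderate,Deregistration,18.2
65-74,Moderate,Ageing,2.78
65-74,Severe,Alive,11.05
65-74,Severe,Entering,48.84
65-74,Severe,Dying,1.13
65-74,Severe,Deregistration,15.36
65-74,Severe,Ageing,14.05
65-74,Fit,FrailtyTransition,6.68
65-74,Mild,FrailtyTransition,8.03
65-74,Moderate,FrailtyTransition,3.33
75-84,Fit,Alive,3.31
75-84,Fit,Entering,19.97
75-84,Fit,Dying,11.2
75-84,Fit,Deregistration,4.13
75-84,Fit,Ageing,10.12
75-84,Mild,Alive,4.32
75-84,Mild,Entering,21.98
75-84,Mild,Dying,10.7
75-84,Mild,Deregistration,6.6
75-84,Mild,Ageing,3.24
75-84,Moderate,Alive,1.38
75-84,Moderate,Entering,23.23
75-84,Moderate,Dying,6.62
75-84,Moderate,Deregistration,12.34
75-84,Moderate,Ageing,7.39
75-84,Severe,Alive,2.33
75-84,Severe,Entering,27.49
75-84,Severe,Dying,1.99
75-84,Severe,Deregistration,4.32
75-84,Severe,Ageing,3.19
75-84,Fit,FrailtyTransition,10.61
75-84,Mild,FrailtyTransition,4.39
75-84,Moderate,FrailtyTransition,5.37
85+,Fit,Alive,9.12
85+,Fit,Entering,12.02
85+,Fit,Dying,8.01
85+,Fit,Deregistration,7.38
85+,Mild,Alive,4.15
85+,Mild,Entering,15.76
85+,Mild,Dying,6.70
85+,Mild,Deregistration,8.23
85+,Moderate,Alive,2.93
85+,Moderate,Entering,19.19
85+,Moderate,Dying,3.09
85+,Moderate,Deregistration,11.13
85+,Severe,Alive,8.92
85+,Severe,Entering,34.64
85+,Severe,Dying,4.43
85+,Severe,Deregistration,4.3
85+,Fit,FrailtyTransition,4.45
85+,Mild,FrailtyTransition,5.97
85+,Moderate,FrailtyTransition,7.38
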