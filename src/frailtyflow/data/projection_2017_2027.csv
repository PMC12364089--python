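band,state,year,percent,number
50-64,Fit,2017,38.36,7689306
65-74,Fit,2017,14.04,2813696
75-84,Fit,2017,4.99,1000342
85+,Fit,2017,1.09,218329
50-64,Mild,2017,9.43,1890524
65-74,Mild,2017,9.34,1871634
75-84,Mild,2017,5.87,1175918
85+,Mild,2017,2.38,476438
50-64,Moderate,2017,1.93,387793
65-74,Moderate,2017,2.60,521885
75-84,Moderate,2017,3.42,686230
85+,Moderate,2017,2.3,460649
50-64,Severe,2017,0.32,63186
65-74,Severe,2017,0.74,148237
75-84,Severe,2017,1.61,323287
85+,Severe,2017,1.59,318311
50-64,Fit,2027,34.85,7580985
65-74,Fit,2027,11.92,2593440
75-84,Fit,2027,4.15,902502
85+,Fit,2027,0.42,92415
50-64,Mild,2027,11.31,2460389
65-74,Mild,2027,10.35,2252318
75-84,Mild,2027,5.95,1294121
85+,Mild,2027,1.39,302014
50-64,Moderate,2027,3.02,657204
65-74,Moderate,2027,2.40,521665
75-84,Moderate,2027,4.02,875014
85+,Moderate,2027,1.77,384709
50-64,Severe,2027,0.64,139944
65-74,Severe,2027,0.96,208367
75-84,Severe,2027,3.61,785707
85+,Severe,2027,3.24,704303
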