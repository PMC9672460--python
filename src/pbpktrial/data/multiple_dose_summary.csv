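# Published multiple-dose (q12h x 5 days + day-6 dose) summary statistics
# (arithmetic mean, SD) for intravenous salvianolic acid A in healthy
# adults. Units: cmax, cavg ng/ml; auc_* h*ng/ml; t_half h;
# fluctuation_pct percent; accumulation_index dimensionless.
cohort_id,dose_mg,n,occasion,parameter_name,mean,sd
RG1,60,8,day1,cmax,2063,264
RG1,60,8,day1,auc_last,2098,265
RG1,60,8,day1,t_half,2.34,1.21
RG1,60,8,day6,cmax,2149,325
RG1,60,8,day6,auc_last,2126,347
RG1,60,8,day6,auc_inf,2164,370
RG1,60,8,day6,t_half,3.40,1.11
RG1,60,8,day6,cavg,178,29
RG1,60,8,day6,auc_tau,2136,347
RG1,60,8,day6,fluctuation_pct,1208,72
RG1,60,8,day6,accumulation_index,1.11,0.08
RG2,120,8,day1,cmax,3513,494
RG2,120,8,day1,auc_last,3545,490
RG2,120,8,day1,t_half,3.11,0.70
RG2,120,8,day6,cmax,3561,463
RG2,120,8,day6,auc_last,3601,557
RG2,120,8,day6,auc_inf,3647,571
RG2,120,8,day6,t_half,4.29,0.89
RG2,120,8,day6,cavg,301,47
RG2,120,8,day6,auc_tau,3607,558
RG2,120,8,day6,fluctuation_pct,1187,49
RG2,120,8,day6,accumulation_index,1.17,0.07
RG3,200,8,day1,cmax,7109,1755
RG3,200,8,day1,auc_last,7137,1999
RG3,200,8,day1,t_half,1.57,0.69
RG3,200,8,day6,cmax,6806,1637
RG3,200,8,day6,auc_last,6954,1832
RG3,200,8,day6,auc_inf,7048,1859
RG3,200,8,day6,t_half,2.87,1.26
RG3,200,8,day6,cavg,583,152
RG3,200,8,day6,auc_tau,6999,1819
RG3,200,8,day6,fluctuation_pct,1167,36
RG3,200,8,day6,accumulation_index,1.08,0.07
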