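# Published single-ascending-dose summary statistics (arithmetic mean, SD)
# for intravenous salvianolic acid A in healthy adults; one row per cohort
# and pharmacokinetic parameter. Units: cmax ng/ml; auc_last and auc_inf
# h*ng/ml; t_half h; vd L; cl L/h. Used as calibration and verification
# targets by the synthetic-trial generator.
cohort_id,dose_mg,n,parameter_name,mean,sd
SG0,10,2,cmax,643,266
SG0,10,2,auc_last,143,114
SG0,10,2,auc_inf,148,118
SG0,10,2,t_half,1.67,1.33
SG0,10,2,vd,161.9,0.9
SG0,10,2,cl,98.4,78.1
SG1,20,6,cmax,599,100
SG1,20,6,auc_last,580,103
SG1,20,6,auc_inf,586,105
SG1,20,6,t_half,1.73,0.86
SG1,20,6,vd,82.5,29.2
SG1,20,6,cl,35.0,6.2
SG2,40,10,cmax,1124,122
SG2,40,10,auc_last,1106,126
SG2,40,10,auc_inf,1114,126
SG2,40,10,t_half,2.20,0.77
SG2,40,10,vd,115.8,46.6
SG2,40,10,cl,36.3,3.5
SG3,80,10,cmax,2770,656
SG3,80,10,auc_last,2920,716
SG3,80,10,auc_inf,2932,719
SG3,80,10,t_half,2.83,0.43
SG3,80,10,vd,116.2,27.6
SG3,80,10,cl,28.7,6.5
SG4,120,10,cmax,3925,679
SG4,120,10,auc_last,4066,788
SG4,120,10,auc_inf,4101,793
SG4,120,10,t_half,1.62,0.41
SG4,120,10,vd,69.0,16.5
SG4,120,10,cl,30.2,5.6
SG5,160,10,cmax,5492,966
SG5,160,10,auc_last,5505,940
SG5,160,10,auc_inf,5550,942
SG5,160,10,t_half,2.55,0.52
SG5,160,10,vd,108.1,25.5
SG5,160,10,cl,29.5,4.3
SG6,200,10,cmax,9344,2382
SG6,200,10,auc_last,9450,2580
SG6,200,10,auc_inf,9530,2590
SG6,200,10,t_half,2.26,0.43
SG6,200,10,vd,70.9,15.6
SG6,200,10,cl,22.4,6.1
SG7,250,10,cmax,12730,5548
SG7,250,10,auc_last,12620,6030
SG7,250,10,auc_inf,12710,6070
SG7,250,10,t_half,2.39,0.55
SG7,250,10,vd,73.4,20.4
SG7,250,10,cl,22.0,5.7
SG8,300,10,cmax,14310,2738
SG8,300,10,auc_last,14560,2970
SG8,300,10,auc_inf,14660,2980
SG8,300,10,t_half,2.92,0.50
SG8,300,10,vd,87.7,14.1
SG8,300,10,cl,21.2,4.1
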