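study,year,n,stand_mean,stand_sd,sit_mean,sit_sd,change_mean,change_sd
DiGioia,2006,84,-1.2,8.2,35.9,12.6,37.1,NR
Philippot,2009,67,4.41,6.68,25.5,9.6,21.1,NR
Lazennec,2011,50,2.4,7.3,16.9,9.1,14.5,NR
Kanawade,2014,85,-0.4,7.4,28.3,9.1,28.7,8.6
Ranawat,2016,68,-3.7,8.8,17.7,11.6,21.4,12.5
Institutional cohort,2019,24,4.2,7.7,23.4,10.6,19.3,9.9
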