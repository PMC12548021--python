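study,y_events,n_treat,x_events,n_control,mean_age,mean_age_sd,pct_male,pct_diabetes
Barcella 2021,20,984,632,127281,40.3,20.8,48.4,4.6
Tzur Bitan 2021,22,649,7,709,51.5,15.4,60.9,17.1
Fond 2021a,4,15,94,1077,63.1,18.5,54.3,23.4
Fond 2021b,211,823,10854,49927,70.3,19.2,56.8,27.8
Jeon 2021,6,159,49,2817,55.4,16.2,41.7,15.1
Nemani 2021,20,75,701,6349,54,18.6,47,25.7
Poblador-Plou 2020,11,40,760,4372,67.7,20.7,41.2,11.9
Rivas-Ramirez 2021,2,18,3,69,51.5,14.8,47.1,4.5
Rodriguez-Molinero 2020,2,4,77,414,65.4,16.6,56.9,23.6
Tyson 2021,5,6,70,144,77.6,10.5,50,34
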