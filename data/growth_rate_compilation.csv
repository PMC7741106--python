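group,category,growth_rate_percent,rate_range_percent,method
Dobe !Kung,ethnographic,0.26,,intrinsic rate of population increase from net reproduction rate
Agta,ethnographic,1.4,,change in census population size 1950-1965
Asmat,ethnographic,1.5,,change in census population size 1956-1973
Hadza,ethnographic,1.6,,combination of methods
Ache,ethnographic,2.0,,change in estimated population size 1930-1970
Australia (40000-0 BP),archaeological,0.045,,approximate maximum rate from smoothed taphonomically corrected SPD
Australia (5000-0 BP),archaeological,0.04,,temporal distribution of radiocarbon dates
Wyoming and Colorado,archaeological,0.04,,exponential model fitted to SPD 13000-6000 BP
South America,archaeological,0.132,0-0.132,logistic growth model fitted to SPD 14000-6000 BP
Kuril Islands,archaeological,0.2,,smoothed SPD 2500-2000 BP
Wyoming (Big Horn basin),archaeological,0.31,0.16-0.31,smoothed SPD; mean annual rates over five major growth periods
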