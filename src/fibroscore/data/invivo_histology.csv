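drug_id,model,study_id,sc_raw,st_raw,scale_max
silymarin,DMN_treatment,Hsu2005,2,1.6,4
thalidomide,DMN_treatment,Chong2006,1.56,0.89,4
tetrandrine,DMN_treatment,Hsu2005,2,1.3,4
colchicine,DMN_treatment,Lee1988,3.8,2.3,4
silymarin,CCl4_treatment,Li2010,3.4,2.5,4
PCN,CCl4_treatment,Marek2005,3.84,2.8,4
malotilate,CCl4_treatment,Dumont1986,3.76,2.67,4
rosmarinic acid,CCl4_treatment,Li2010,3.4,2.1,4
pioglitazone,CCl4_treatment,Yuan2004,4,2.63,4
taurine,CCl4_treatment,Tasci2008a,3.33,1.33,4
PCN,CCl4_preventive,Marek2005,3.6,3.68,4
taurine,CCl4_preventive,Tasci2008b,3.03,1.87,4
melatonin,CCl4_preventive,Hong2009,3.38,2.25,4
oxymatrine,CCl4_preventive,Wu2004,3.76,2.43,4
silymarin,CCl4_preventive,Jeong2005,4,2.5,4
malotilate,CCl4_preventive,Dumont1986,2.91,0.76,4
EGCG,CCl4_preventive,Zhen2007,3.58,1.5,4
pioglitazone,CCl4_preventive,Yuan2004,4,1.94,4
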