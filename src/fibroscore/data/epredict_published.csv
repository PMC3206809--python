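drug_id,e_predict
taxifolin,0
taurine,0
curcumin,0
resveratrol,0
silymarin,0
minoxidil sulphate,0
simvastatin,0
genistein,0
lovastatin,0
PTK/ZK,0
Y27632,0
rotenone,0
AG1295,0
paclitaxel,0
aphidicolin,0
nocodazole,0
pentoxifylline,5175
matrine,5295
astragaloside IV,5496
thalidomide,6263
colchicine,6487
TGFb inhibitor V,6974
gliotoxin,7086
PCN,8203
camostat mesylate,8231
imatinib mesylate,8454
oxymatrine,8528
pirfenidone,8837
minoxidil,9069
AG1296,9154
somatostatin,10057
MG132,10669
tetrandrine,10747
telmisartan,11467
malotilate,12941
melatonin,13728
fasudil HCl,14295
olmesartan medoxomil,15959
silybin,18138
TGFb inhibitor III,18315
tranilast,19594
EGCG,19704
bortezomib,21047
rosmarinic acid,21435
berberine chloride,21983
staurosporine,25015
glycyrrhizin,25728
pioglitazone,35226
sulfasalazine,39437
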