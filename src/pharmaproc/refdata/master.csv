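medicine_code,name,strength_mg,dosage_form
ANA1,Anastrozole,1,tablet
DOC40,Docetaxel,40,ampoule
EXE25,Exemestane,25,capsule
LET25,Letrozole,2.5,tablet
PAC6,Paclitaxel,6,ampoule
TAM20,Tamoxifen,20,tablet
TRA440,Trastuzumab,440,ampoule
VIN10,Vinorelbine,10,ampoule/capsule
VIN20,Vinorelbine,20,ampoule/capsule
VIN30,Vinorelbine,30,ampoule/capsule
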