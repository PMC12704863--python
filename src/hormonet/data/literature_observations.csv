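condition,node,call,source
E2,ERK12,no_change,text: literature found no ERK12 change under E2 alone
E2,CellArea,no_change,text: literature found no CellArea change under E2 alone
E2,PI3K,no_change,text: literature found no PI3K change under E2 alone
Strain,PI3K,increase,text: literature reports strain increases PI3K
AngII,PI3K,increase,text: literature reports AngII increases PI3K
ET1,PI3K,decrease,text: literature reports ET-1 decreases PI3K
AngII,AMPKf,increase,text: literature reports AngII activates AMPK in females
AngII,MCIP1,no_change,text: AngII alone had no effect on MCIP1
AngII+E2,MCIP1,increase,text: AngII with E2 induced an MCIP1 increase
Strain,CellArea,increase,text: strain is a pro-hypertrophic stimulus
AngII,CellArea,increase,text: AngII is a pro-hypertrophic stimulus
ET1,CellArea,increase,text: ET-1 is a pro-hypertrophic stimulus
T,CellArea,increase,text: testosterone is pro-hypertrophic
Strain+E2,CellArea,decrease,text: E2 mitigates strain-driven hypertrophy
AngII+E2,CellArea,decrease,text: E2 mitigates AngII-driven hypertrophy
ET1+E2,CellArea,decrease,text: E2 mitigates ET-1 driven hypertrophy
Strain+T,CellArea,increase,text: T exacerbates strain-driven hypertrophy
AngII+T,CellArea,increase,text: T exacerbates AngII-driven hypertrophy
Strain+E2,ERK12,decrease,text: E2 attenuates strain-driven ERK12 activation
AngII+E2,ERK12,decrease,text: E2 attenuates AngII-driven ERK12 activation
ET1+E2,ERK12,decrease,text: E2 attenuates ET-1 driven ERK12 activation
Strain+E2,p38,decrease,text: E2 attenuates strain-driven p38 activation
E2,eNOS,increase,reconstruction: estradiol activates eNOS in females
E2,NO,increase,reconstruction: eNOS-derived NO downstream of estradiol
E2,cGMP,increase,reconstruction: NO-cGMP axis downstream of estradiol
T,IP3,increase,reconstruction: testosterone activates IP3
T,CaN,increase,reconstruction: testosterone supplements calcineurin activation
T,AR,increase,reconstruction: androgen receptor engagement
T,NFAT,increase,reconstruction: androgen-driven NFAT activation
T,mTOR,increase,reconstruction: androgen-mTOR growth axis
T,AMPKm,increase,reconstruction: androgen-driven AMPK arm in males
T,Hk2,increase,reconstruction: Hk2 downstream of AMPK in males
T,Pfk2,increase,reconstruction: Pfk2 downstream of AMPK in males
Strain,p38,increase,reconstruction: strain-driven p38 activation
Strain,ERK12,increase,reconstruction: strain-driven ERK12 activation
AngII,ERK12,increase,reconstruction: AngII-driven ERK12 activation
ET1,ERK12,increase,reconstruction: ET-1 driven ERK12 activation
AngII,CaN,increase,reconstruction: AngII activation of calcineurin
AngII,CamKII,increase,reconstruction: AngII-driven calcium/CamKII signaling
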