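rule,weight,n,ec50,source,sex_evidence
=> E2,0.15,1.4,0.5,input drive; weight from shared baseline calibration,
=> T,0.15,1.4,0.5,input drive; weight from shared baseline calibration,
=> Strain,0.15,1.4,0.5,input drive; weight from shared baseline calibration,
=> AngII,0.15,1.4,0.5,input drive; weight from shared baseline calibration,
=> ET1,0.15,1.4,0.5,input drive; weight from shared baseline calibration,
E2 => ER,1,1.4,0.5,estrogen receptor engagement,female
T => AR,1,1.4,0.5,androgen receptor engagement,male
T => IP3,1,1.4,0.5,direct activation of IP3 by testosterone,male
IP3 => Ca,1,1.4,0.5,IP3-mediated calcium release,
AngII => Ca,1,1.4,0.5,AngII-stimulated calcium entry (pathway completion),
Ca => CamKII,1,1.4,0.5,calcium-dependent CamKII activation,
Ca & !PKG1 => CaN,1,1.4,0.5,calcium activation of calcineurin; PKG1 suppresses the calcium arm (pathway completion),
AngII => CaN,1,1.4,0.5,AngII activation of calcineurin,
T => CaN,1,1.4,0.5,testosterone supplements AngII activation of calcineurin,male
ET1 => CaN,1,1.4,0.5,ET-1 activation of calcineurin,
Strain & !E2 => p38,1,1.4,0.5,strain-driven p38 activation attenuated by estradiol,female
Strain & !E2 => ERK12,1,1.4,0.5,strain-driven ERK1/2 activation attenuated by estradiol,female
AngII & !E2 => ERK12,1,1.4,0.5,AngII-driven ERK1/2 activation attenuated by estradiol,female
AngII & T => ERK12,1,1.4,0.5,testosterone amplifies AngII-driven ERK1/2 activation (AR-knockdown inference),male
ET1 & !E2 => ERK12,1,1.4,0.5,ET-1 driven ERK1/2 activation attenuated by estradiol,female
E2 & !Strain & !ET1 => PI3K,1,1.4,0.5,estradiol attenuates strain and ET-1 inhibition of PI3K/Akt,female
PI3K => Akt,1,1.4,0.5,canonical PI3K/Akt axis,
!p38 & !AR => GSK3B,1,1.4,0.5,constitutive GSK3β inactivated by p38 and androgen signaling (pathway completion),
ERK12 & CaN => NFAT,1,1.4,0.5,synergistic NFAT activation by ERK1/2 and calcineurin,
!GSK3B => NFAT,1,1.4,0.5,GSK3β inhibition of NFAT,
CamKII => NFAT,1,1.4,0.5,CamKII facilitation of NFAT signaling (pathway completion),
ER => eNOS,1,1.4,0.5,estradiol-receptor activation of eNOS,female
eNOS => NO,1,1.4,0.5,eNOS-derived nitric oxide,
NO => cGMP,1,1.4,0.5,NO-stimulated guanylate cyclase,
cGMP => PKG1,1,1.4,0.5,cGMP-dependent protein kinase activation,
E2 & AngII => AMPKf,1,1.4,0.5,estradiol and AngII act jointly on AMPK,female
AR => AMPKm,1,1.4,0.5,androgen-driven AMPK arm,male
AMPKm => Hk2,1,1.4,0.5,hexokinase 2 downstream of AMPK,male
AMPKm => Pfk2,1,1.4,0.5,phosphofructokinase 2 downstream of AMPK,male
AMPKf => MCIP1,1,1.4,0.5,MCIP1 induction downstream of the female AMPK arm,female
ERK12 => GATA4,1,1.4,0.5,ERK1/2 activation of GATA4 (pathway completion),
AR => mTOR,1,1.4,0.5,androgen-mTOR growth axis (pathway completion),male
NFAT & !PKG1 => CellArea,1,1.4,0.5,NFAT-driven hypertrophic transcription opposed by PKG1,
ERK12 => CellArea,1,1.4,0.5,ERK1/2-driven hypertrophic growth,
CamKII => CellArea,1,1.4,0.5,CamKII-driven hypertrophic growth,
mTOR & !PKG1 => CellArea,1,1.4,0.5,mTOR-driven growth opposed by PKG1,
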