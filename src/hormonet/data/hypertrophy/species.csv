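name,display_name,y0,ymax,tau,role
E2,E2,0,1,0.1,input
T,T,0,1,0.1,input
Strain,Strain,0,1,0.1,input
AngII,AngII,0,1,0.1,input
ET1,ET-1,0,1,0.1,input
ER,ER,0,1,0.1,
AR,AR,0,1,0.1,
IP3,IP3,0,1,0.1,
Ca,Ca2+,0,1,0.1,
CamKII,CamKII,0,1,0.1,
CaN,CaN,0,1,0.1,
p38,p38,0,1,0.1,
ERK12,ERK1/2,0,1,0.1,
PI3K,PI3K,0,1,0.1,
Akt,Akt,0,1,0.1,
GSK3B,GSK3β,0,1,0.1,
NFAT,NFAT,0,1,0.1,
GATA4,GATA4,0,1,0.1,
eNOS,eNOS,0,1,0.1,
NO,NO,0,1,0.1,
cGMP,cGMP,0,1,0.1,
PKG1,PKG1,0,1,0.1,
AMPKf,AMPKf,0,1,0.1,
AMPKm,AMPKm,0,1,0.1,
Hk2,Hk2,0,1,0.1,
Pfk2,Pfk2,0,1,0.1,
MCIP1,MCIP1,0,1,0.1,
mTOR,mTOR,0,1,0.1,
CellArea,CellArea,0,1,300,output
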