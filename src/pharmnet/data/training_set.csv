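name,ic50_uM,label,activity_class,ic50_source,reference
picropodophyllin,0.04,active,most_active,reported,text
NVP-AEW541,0.15,active,most_active,reconstructed,figure
BMS-754807,0.3,active,most_active,reconstructed,figure
GSK1838705A,0.5,active,most_active,reconstructed,figure
NVP-ADW742,0.8,active,moderately_active,reconstructed,figure
BMS-536924,1.0,active,moderately_active,reconstructed,figure
BMS-554417,2.0,active,moderately_active,reconstructed,figure
OSI-906,2.5,active,moderately_active,reconstructed,figure
AG1024,3.0,active,moderately_active,reconstructed,figure
AG538,4.0,active,moderately_active,reconstructed,figure
TAE226,5.0,active,moderately_active,reconstructed,figure
PQ401,6.0,active,moderately_active,reconstructed,figure
KW-2450,8.0,active,moderately_active,reconstructed,figure
XL228,10.0,active,moderately_active,reconstructed,figure
nordihydroguaiaretic-acid,12.0,active,moderately_active,reconstructed,figure
INSM-18,15.0,active,moderately_active,reconstructed,figure
genistein,20.0,active,moderately_active,reconstructed,figure
quercetin,25.0,active,less_active,reconstructed,figure
luteolin,30.0,active,less_active,reconstructed,figure
apigenin,45.0,active,less_active,reconstructed,figure
fisetin,60.0,active,less_active,reconstructed,figure
daidzein,100.0,inactive,inactive,reconstructed,figure
chrysin,200.0,inactive,inactive,reconstructed,figure
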