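symbol	cor_ccle	cor_tcga
APMAP	0.562	0.35
CDK4	0.364	0.36
CECR5	0.383	0.359
CNNM1	0.388	0.353
DLX6	0.373	0.357
FLVCR1	0.378	0.432
GLI2	0.38	0.364
GTPBP3	0.355	0.372
MTA1	0.367	0.385
PEX5	0.376	0.363
PMS2P1	0.426	0.406
PNCK	0.396	0.458
SLC30A3	0.449	0.351
SMYD3	0.47	0.364
TFB2M	0.382	0.357
TMEM161A	0.357	0.369
TMEM97	0.478	0.371
USP39	0.409	0.392
VMA21	0.373	0.371
ZNF74	0.423	0.366
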