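# Synthetic fixture contaminant list. Contaminant names are the classes
# routinely scanned for in ZooMS work (keratins, trypsin autolysis, matrix
# clusters, casein, serum albumin); the masses are synthetic test stand-ins,
# NOT curated values. Schema: name,mass
name,mass
porcine trypsin autolysis,842.51
porcine trypsin autolysis,1045.56
porcine trypsin autolysis,2211.10
human keratin,1165.59
human keratin,1475.79
human keratin,2383.95
non-human keratin,1193.65
CHCA matrix cluster,855.03
CHCA matrix cluster,877.04
bovine casein alpha-S1,1267.70
bovine serum albumin,1479.80
bovine serum albumin,1639.94
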