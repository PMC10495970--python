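water
ethyl acetate
tetrahydrofuran
dichloromethane
methanol
ethanol
acetone
acetonitrile
toluene
hexane
heptane
diethyl ether
petroleum ether
dimethylformamide
dimethyl sulfoxide
1,4-dioxane
chloroform
isopropanol
2-methyltetrahydrofuran
methyl tert-butyl ether
xylene
pyridine
n-butanol
1,2-dimethoxyethane
brine
saturated aqueous sodium chloride
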