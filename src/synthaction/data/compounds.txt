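3-cyano-4-((1-methylethyl)oxy)benzoic acid
1-benzyl-2-(chloromethyl)pyrrolidine
4-bromoanisole
2-aminopyridine
4-nitrobenzaldehyde
methyl 4-bromobenzoate
benzoic acid
4-fluoroaniline
2-chloro-5-nitropyridine
tert-butyl 4-aminopiperidine-1-carboxylate
3-bromopyridine
4-methoxyphenylboronic acid
2,4-dichloropyrimidine
N-Boc-piperazine
ethyl 2-oxocyclopentanecarboxylate
4-(trifluoromethyl)benzaldehyde
2-bromothiophene
5-bromo-2-methoxypyridine
1-methylpiperazine
cyclopropylamine
4-chlorobenzyl chloride
3,4-dimethoxybenzaldehyde
2-naphthol
4-hydroxybenzonitrile
methyl 3-aminobenzoate
2-fluoro-4-bromotoluene
N,N-diisopropylethylamine
triethylamine
EDC
HOBt
HATU
4-dimethylaminopyridine
di-tert-butyl dicarbonate
benzyl bromide
iodomethane
sodium borohydride
lithium aluminium hydride
sodium hydride
potassium carbonate
cesium carbonate
sodium bicarbonate
ammonium chloride
hydrochloric acid
sulfuric acid
acetic acid
trifluoroacetic acid
sodium hydroxide
lithium hydroxide
palladium on carbon
tetrakis(triphenylphosphine)palladium(0)
copper(I) iodide
zinc dust
2-(4-chlorophenyl)acetic acid
3-methyl-1H-pyrazole
5-amino-1-methyl-1H-pyrazole
2-bromo-4'-methylacetophenone
4-piperidone hydrochloride
morpholine
pyrrolidine
piperidine
aniline
benzylamine
cyclohexylamine
2-phenylethylamine
4-methoxyaniline
3-chloroaniline
2,6-lutidine
imidazole
1H-benzimidazole
2-mercaptobenzothiazole
thiophene-2-carboxylic acid
furan-2-carbaldehyde
1H-indole-3-carbaldehyde
quinoline-8-ol
isoquinoline
2-acetylpyridine
4-acetamidophenol
salicylaldehyde
vanillin
trans-cinnamic acid
phenylacetic acid
4-toluenesulfonyl chloride
methanesulfonyl chloride
acetyl chloride
benzoyl chloride
oxalyl chloride
thionyl chloride
phosphorus oxychloride
ethyl chloroformate
2-chloroacetamide
glycine ethyl ester hydrochloride
L-proline
N-methylmorpholine
1,8-diazabicyclo[5.4.0]undec-7-ene
triphenylphosphine
diethyl azodicarboxylate
2-iodoxybenzoic acid
manganese dioxide
potassium permanganate
m-chloroperoxybenzoic acid
hydrogen peroxide
hydrazine hydrate
hydroxylamine hydrochloride
O-methylhydroxylamine hydrochloride
2-(methylthio)aniline
ethyl 4,4,4-trifluoroacetoacetate
methyl propiolate
dimethyl malonate
diethyl oxalate
2-cyanoacetamide
malononitrile
nitromethane
2-nitropropane
allyl bromide
propargyl bromide
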