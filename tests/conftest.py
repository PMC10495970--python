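import pytest

from synthaction import synthcorpus as sc
from synthaction.tokenize import train_subword

# Worked examples of the structured-action format: five (sentence,
# structured) pairs exercising MAKESOLUTION/SLN, amounts, keep-phases,
# PURIFY solvent systems and YIELD.
TABLE1 = [
    (
        "To a solution of 3-cyano-4-((1-methylethyl)oxy)benzoic acid (200 mg)"
        " in tetrahydrofuran (THF) (10 mL) was added EDC (374 mg) and HOBt"
        " (299 mg).",
        "MAKESOLUTION with 3-cyano-4-((1-methylethyl)oxy)benzoic acid (200 mg)"
        " and tetrahydrofuran (THF) (10 mL); ADD SLN; ADD EDC (374 mg);"
        " ADD HOBt (299 mg).",
    ),
    (
        "The resulting orange solution was partitioned between dichloromethane"
        " (10 mL) and water (10 mL)",
        "PARTITION with dichloromethane (10 mL) and water (10 mL).",
    ),
    (
        "Ethanol and water are added to produce a solid which is collected by"
        " filtration.",
        "ADD Ethanol; ADD water; FILTER keep precipitate.",
    ),
    (
        "The solution was quenched with saturated aqueous NH4Cl and extracted"
        " with CH2Cl2.",
        "QUENCH with saturated aqueous NH4Cl; EXTRACT with CH2Cl2.",
    ),
    (
        "The resulting mixture was filtered and the filtrate was concentrated"
        " and the residue was purified by flash column chromatography"
        " (ethylacetate/petroleum ether gradient) to afford"
        " 1-benzyl-2-(chloromethyl)pyrrolidine.",
        "FILTER keep filtrate; CONCENTRATE; PURIFY: ethyl acetate:petroleum"
        " ether; YIELD 1-benzyl-2-(chloromethyl)pyrrolidine.",
    ),
]


@pytest.fixture(scope="session")
def table1_structured():
    return [structured for _, structured in TABLE1]


@pytest.fixture(scope="session")
def small_pairs():
    """A small deterministic paired corpus shared across tests."""
    return sc.generate_pairs(sc.GeneratorConfig(n=400, seed=123))


@pytest.fixture(scope="session")
def small_tokenizer(small_pairs):
    corpus = [p.sentence for p in small_pairs] + [
        p.structured for p in small_pairs]
    return train_subword(corpus, 600)
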