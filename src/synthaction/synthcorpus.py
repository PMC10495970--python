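"""Synthetic paired-corpus generator for desk-scale experiments.

Real training corpora for this task are built from patent paragraphs paired
with structured action strings.  This module emulates that material: it
composes synthesis sentences from clause templates ("a solution of X (200 mg)
in THF (10 mL) was prepared, then the mixture was stirred at 25 °C for 2 h")
together with their gold structured counterparts, records slot provenance so
the four augmentation operators (temperature / duration / solvent / compound
substitution) can rewrite both sides identically, and provides negative
paragraphs for the classification task plus the 80/10/10 dataset splitter.

Because every template couples a sentence pattern to a structured pattern,
the template set is invertible: :func:`rule_oracle_translate` maps a
generated sentence back to its gold structured string without any learned
model, which gives downstream stages a converter-independent test path.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from .errors import AugmentError, ConfigError, SizeError
from .filters import ParagraphRecord

__all__ = [
    "CorpusPair",
    "GeneratorConfig",
    "Lexicons",
    "default_lexicons",
    "generate_pairs",
    "generate_negatives",
    "generate_classification_set",
    "augment",
    "split",
    "rule_oracle_translate",
    "write_pairs_tsv",
    "read_pairs_tsv",
    "write_pairs_jsonl",
    "read_pairs_jsonl",
    "DEFAULT_ACTION_WEIGHTS",
]

AUGMENT_CLASSES = ("temperature", "duration", "solvent", "compound")
MAX_AUGMENT = 4

# Default action sampling weights: per-action frequencies observed in a large
# patent-derived corpus (counts in the hundreds of thousands for Add/Stir/
# Concentrate down to ~1.4k for Sonicate).
DEFAULT_ACTION_WEIGHTS = {
    "Add": 2_249_260,
    "Stir": 671_005,
    "Concentrate": 656_695,
    "Yield": 618_280,
    "Wash": 506_832,
    "MakeSolution": 476_329,
    "CollectLayer": 364_382,
    "Filter": 352_100,
    "DrySolution": 336_816,
    "Purify": 323_716,
    "SetTemperature": 275_622,
    "Extract": 245_546,
    "NoAction": 207_310,
    "FollowOtherProcedure": 168_541,
    "Reflux": 102_683,
    "PH": 95_297,
    "PhaseSeparation": 67_165,
    "Wait": 65_751,
    "DrySolid": 64_692,
    "Recrystallize": 62_959,
    "Quench": 49_396,
    "InvalidAction": 44_904,
    "Partition": 34_534,
    "Triturate": 29_702,
    "Degas": 24_100,
    "Microwave": 11_988,
    "OtherLanguage": 1_936,
    "Sonicate": 1_447,
}

_AMOUNT_NUMBERS = (5, 10, 15, 20, 25, 30, 40, 50, 60, 75, 80, 100, 120, 150,
                   200, 250, 299, 300, 350, 374, 400, 500, 600, 750)
_AMOUNT_UNITS = ("mg", "g", "mL", "L", "mmol", "mol")
_TEMP_NUMBERS = (-78, -40, -20, -10, 0, 5, 10, 20, 25, 30, 40, 50, 60, 70,
                 80, 90, 100, 110, 120, 150)
_DURATION_NUMBERS = (1, 2, 3, 4, 5, 6, 8, 10, 12, 15, 16, 18, 20, 24, 30,
                     36, 45, 48, 90)
_QUENCH_AGENTS = ("saturated aqueous NH4Cl", "water", "ice water",
                  "saturated aqueous sodium bicarbonate", "1 M hydrochloric acid")
_DRYING_AGENTS = ("sodium sulfate", "magnesium sulfate")
_GASES = ("nitrogen", "argon")
_PH_VALUES = tuple(range(1, 13))


def _read_data_lines(name: str) -> tuple[str, ...]:
    text = resources.files("synthaction.data").joinpath(name).read_text("utf-8")
    return tuple(line.strip() for line in text.splitlines() if line.strip())


@dataclass
class Lexicons:
    compounds: tuple[str, ...]
    solvents: tuple[str, ...]
    temperature_notations: tuple[str, ...]
    duration_units: tuple[str, ...]
    quench_agents: tuple[str, ...] = _QUENCH_AGENTS
    drying_agents: tuple[str, ...] = _DRYING_AGENTS
    gases: tuple[str, ...] = _GASES

    def validate(self) -> None:
        for name in ("compounds", "solvents", "temperature_notations",
                     "duration_units"):
            if not getattr(self, name):
                raise ConfigError(f"lexicon {name!r} is empty")


def default_lexicons() -> Lexicons:
    return Lexicons(
        compounds=_read_data_lines("compounds.txt"),
        solvents=_read_data_lines("solvents.txt"),
        temperature_notations=_read_data_lines("temperature_notations.txt"),
        duration_units=_read_data_lines("duration_units.txt"),
    )


@dataclass
class GeneratorConfig:
    n: int = 1000
    seed: int = 0
    action_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_ACTION_WEIGHTS))
    lexicons: Optional[Lexicons] = None
    positive_fraction: float = 0.336
    max_clauses_per_sentence: int = 3

    def resolved_lexicons(self) -> Lexicons:
        lex = self.lexicons or default_lexicons()
        lex.validate()
        return lex

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be >= 0")
        if not self.action_weights or sum(self.action_weights.values()) <= 0:
            raise ConfigError("action weights must sum to a positive value")
        if any(w < 0 for w in self.action_weights.values()):
            raise ConfigError("action weights must be nonnegative")
        if not (0.0 < self.positive_fraction < 1.0):
            raise ConfigError("positive_fraction must be in (0, 1)")
        if self.max_clauses_per_sentence < 1:
            raise ConfigError("max_clauses_per_sentence must be >= 1")


@dataclass
class CorpusPair:
    sentence: str
    structured: str
    slots: dict = field(default_factory=dict)
    origin: str = "template"
    parent_id: Optional[str] = None
    id: Optional[str] = None
    actions: list = field(default_factory=list)  # sampled primary actions


# --------------------------------------------------------------------------
# Clause templates.  `sent` and `struct` share slot names; `kinds` maps each
# slot to its lexicon kind, which is what the augmentation operators key on.


@dataclass(frozen=True)
class _Template:
    name: str
    action: str  # primary action used for weight sampling
    sent: str
    struct: str
    kinds: dict


_TEMPLATES: list[_Template] = [
    _Template("add_amount", "Add",
              "{c0} ({a0}) was added",
              "ADD {c0} ({a0})", {"c0": "compound", "a0": "amount"}),
    _Template("add_to_mixture", "Add",
              "to the mixture was added {c0} ({a0})",
              "ADD {c0} ({a0})", {"c0": "compound", "a0": "amount"}),
    _Template("add_dropwise", "Add",
              "{c0} was added dropwise",
              "ADD {c0}", {"c0": "compound"}),
    _Template("makesolution", "MakeSolution",
              "a solution of {c0} ({a0}) in {s0} ({a1}) was prepared",
              "MAKESOLUTION with {c0} ({a0}) and {s0} ({a1}); ADD SLN",
              {"c0": "compound", "a0": "amount", "s0": "solvent",
               "a1": "amount"}),
    _Template("stir_temp_time", "Stir",
              "the mixture was stirred at {t0} for {d0}",
              "STIR at {t0} for {d0}",
              {"t0": "temperature", "d0": "duration"}),
    _Template("stir_time", "Stir",
              "the reaction mixture was stirred for {d0}",
              "STIR for {d0}", {"d0": "duration"}),
    _Template("concentrate_rp", "Concentrate",
              "the solvent was removed under reduced pressure",
              "CONCENTRATE", {}),
    _Template("concentrate_vacuo", "Concentrate",
              "the mixture was concentrated in vacuo",
              "CONCENTRATE", {}),
    _Template("yield_amount", "Yield",
              "the product {c0} ({a0}) was obtained",
              "YIELD {c0} ({a0})", {"c0": "product", "a0": "amount"}),
    _Template("purify_yield", "Yield",
              "the residue was purified by flash column chromatography "
              "({s0}:{s1}) to afford {c0}",
              "PURIFY: {s0}:{s1}; YIELD {c0}",
              {"s0": "solvent", "s1": "solvent", "c0": "product"}),
    _Template("wash", "Wash",
              "the organic layer was washed with {s0}",
              "WASH with {s0}", {"s0": "solvent"}),
    _Template("drysolution", "DrySolution",
              "the organic phase was dried over {g0}",
              "DRYSOLUTION over {g0}", {"g0": "drying"}),
    _Template("filter_plain", "Filter",
              "the mixture was filtered",
              "FILTER", {}),
    _Template("filter_precipitate", "Filter",
              "the precipitate was collected by filtration",
              "FILTER keep precipitate", {}),
    _Template("filter_filtrate", "Filter",
              "the mixture was filtered and the filtrate was collected",
              "FILTER keep filtrate", {}),
    _Template("purify", "Purify",
              "the crude material was purified by column chromatography "
              "({s0}:{s1})",
              "PURIFY: {s0}:{s1}", {"s0": "solvent", "s1": "solvent"}),
    _Template("settemp_cool", "SetTemperature",
              "the mixture was cooled to {t0}",
              "SETTEMPERATURE {t0}", {"t0": "temperature"}),
    _Template("settemp_heat", "SetTemperature",
              "the solution was heated to {t0}",
              "SETTEMPERATURE {t0}", {"t0": "temperature"}),
    _Template("extract", "Extract",
              "the aqueous layer was extracted with {s0} ({a0})",
              "EXTRACT with {s0} ({a0})", {"s0": "solvent", "a0": "amount"}),
    _Template("noaction", "NoAction",
              "the reaction progress was monitored by TLC",
              "NOACTION", {}),
    _Template("collect_organic", "CollectLayer",
              "the organic layer was separated",
              "COLLECTLAYER keep organic", {}),
    _Template("collect_aqueous", "CollectLayer",
              "the aqueous layer was separated",
              "COLLECTLAYER keep aqueous", {}),
    _Template("reflux", "Reflux",
              "the mixture was heated to reflux for {d0}",
              "REFLUX for {d0}", {"d0": "duration"}),
    _Template("ph", "PH",
              "the pH was adjusted to {p0}",
              "PH to {p0}", {"p0": "ph"}),
    _Template("phasesep", "PhaseSeparation",
              "the layers were separated",
              "PHASESEPARATION", {}),
    _Template("wait", "Wait",
              "the mixture was allowed to stand for {d0}",
              "WAIT for {d0}", {"d0": "duration"}),
    _Template("drysolid", "DrySolid",
              "the solid was dried under vacuum",
              "DRYSOLID", {}),
    _Template("recrystallize", "Recrystallize",
              "the crude product was recrystallized from {s0}",
              "RECRYSTALLIZE with {s0}", {"s0": "solvent"}),
    _Template("quench", "Quench",
              "the reaction was quenched with {q0}",
              "QUENCH with {q0}", {"q0": "quench"}),
    _Template("followother", "FollowOtherProcedure",
              "the intermediate was prepared following the general procedure",
              "FOLLOWOTHERPROCEDURE", {}),
    _Template("partition", "Partition",
              "the residue was partitioned between {s0} ({a0}) and {s1} ({a1})",
              "PARTITION with {s0} ({a0}) and {s1} ({a1})",
              {"s0": "solvent", "a0": "amount", "s1": "solvent",
               "a1": "amount"}),
    _Template("triturate", "Triturate",
              "the solid was triturated with {s0}",
              "TRITURATE with {s0}", {"s0": "solvent"}),
    _Template("degas", "Degas",
              "the mixture was degassed with {g0}",
              "DEGAS with {g0}", {"g0": "gas"}),
    _Template("microwave", "Microwave",
              "the mixture was heated in a microwave reactor at {t0} for {d0}",
              "MICROWAVE at {t0} for {d0}",
              {"t0": "temperature", "d0": "duration"}),
    _Template("sonicate", "Sonicate",
              "the suspension was sonicated for {d0}",
              "SONICATE for {d0}", {"d0": "duration"}),
    _Template("invalidaction", "InvalidAction",
              "the transformation proceeds via nucleophilic substitution",
              "INVALIDACTION", {}),
    _Template("otherlanguage", "OtherLanguage",
              "die Mischung wurde bei Raumtemperatur geruehrt",
              "OTHERLANGUAGE", {}),
]

_TEMPLATES_BY_ACTION: dict[str, list[_Template]] = {}
for _t in _TEMPLATES:
    _TEMPLATES_BY_ACTION.setdefault(_t.action, []).append(_t)

_CONNECTIVE = ", then "


def _template_regex(t: _Template) -> re.Pattern:
    pattern = re.escape(t.sent)
    for slot in t.kinds:
        pattern = pattern.replace(re.escape("{%s}" % slot),
                                  f"(?P<{slot}>.+?)")
    return re.compile("^" + pattern + "$", flags=re.IGNORECASE)


_TEMPLATE_REGEXES = [(t, _template_regex(t)) for t in _TEMPLATES]


def _sample_slot(kind: str, rng: np.random.Generator, lex: Lexicons) -> str:
    if kind in ("compound", "product"):
        return str(rng.choice(lex.compounds))
    if kind == "solvent":
        return str(rng.choice(lex.solvents))
    if kind == "amount":
        return (f"{_AMOUNT_NUMBERS[rng.integers(len(_AMOUNT_NUMBERS))]} "
                f"{_AMOUNT_UNITS[rng.integers(len(_AMOUNT_UNITS))]}")
    if kind == "temperature":
        if rng.random() < 0.2:
            return "room temperature"
        num = _TEMP_NUMBERS[rng.integers(len(_TEMP_NUMBERS))]
        notation = lex.temperature_notations[
            rng.integers(len(lex.temperature_notations))]
        return f"{num} {notation}"
    if kind == "duration":
        if rng.random() < 0.1:
            return "overnight"
        num = _DURATION_NUMBERS[rng.integers(len(_DURATION_NUMBERS))]
        unit = lex.duration_units[rng.integers(len(lex.duration_units))]
        return f"{num} {unit}"
    if kind == "quench":
        return str(rng.choice(lex.quench_agents))
    if kind == "drying":
        return str(rng.choice(lex.drying_agents))
    if kind == "gas":
        return str(rng.choice(lex.gases))
    if kind == "ph":
        return str(_PH_VALUES[rng.integers(len(_PH_VALUES))])
    raise ConfigError(f"unknown slot kind {kind!r}")


def _sample_pair(
    rng: np.random.Generator,
    lex: Lexicons,
    actions: list[str],
    probs: np.ndarray,
    max_clauses: int,
    pair_id: str,
) -> CorpusPair:
    n_clauses = int(rng.integers(1, max_clauses + 1))
    sent_parts: list[str] = []
    struct_parts: list[str] = []
    slots: dict[str, str] = {}
    counters: dict[str, int] = {}
    primary: list[str] = []
    for _ in range(n_clauses):
        action = actions[int(rng.choice(len(actions), p=probs))]
        options = _TEMPLATES_BY_ACTION[action]
        template = options[int(rng.integers(len(options)))]
        values = {}
        for slot, kind in template.kinds.items():
            surface = _sample_slot(kind, rng, lex)
            values[slot] = surface
            idx = counters.get(kind, 0)
            counters[kind] = idx + 1
            slots[f"{kind}_{idx}"] = surface
        sent_parts.append((template.sent.format(**values),
                           template.sent.startswith("{")))
        struct_parts.append(template.struct.format(**values))
        primary.append(action)
    sentence = _CONNECTIVE.join(part for part, _ in sent_parts)
    # capitalize only when the sentence opens with literal template text,
    # so slot surfaces stay verbatim on both sides (oracle invertibility)
    if not sent_parts[0][1]:
        sentence = sentence[0].upper() + sentence[1:]
    sentence = sentence + "."
    structured = "; ".join(struct_parts) + "."
    return CorpusPair(sentence=sentence, structured=structured, slots=slots,
                      origin="template", id=pair_id, actions=primary)


def generate_pairs(cfg: GeneratorConfig) -> list[CorpusPair]:
    """Generate ``cfg.n`` (sentence, structured) pairs, seeded and exact."""
    cfg.validate()
    lex = cfg.resolved_lexicons()
    unknown = set(cfg.action_weights) - set(_TEMPLATES_BY_ACTION)
    if unknown:
        raise ConfigError(f"no templates for actions: {sorted(unknown)}")
    actions = sorted(cfg.action_weights)
    weights = np.array([cfg.action_weights[a] for a in actions], dtype=float)
    probs = weights / weights.sum()
    rng = np.random.default_rng(cfg.seed)
    return [
        _sample_pair(rng, lex, actions, probs, cfg.max_clauses_per_sentence,
                     pair_id=f"pair-{i:06d}")
        for i in range(cfg.n)
    ]


# --------------------------------------------------------------------------
# Augmentation

_KIND_FOR_CLASS = {
    "temperature": ("temperature",),
    "duration": ("duration",),
    "solvent": ("solvent",),
    "compound": ("compound", "product"),
}


def _augmentable_slots(pair: CorpusPair, cls: str) -> list[str]:
    kinds = _KIND_FOR_CLASS[cls]
    return [k for k in pair.slots if k.rsplit("_", 1)[0] in kinds]


def _replacement(cls: str, old: str, rng: np.random.Generator,
                 lex: Lexicons) -> str:
    for _ in range(64):
        value = _sample_slot("compound" if cls == "compound" else cls, rng, lex)
        if value != old:
            return value
    raise AugmentError(f"no alternative value available for class {cls!r}")


def augment(
    pair: CorpusPair,
    k: int,
    lexicons: Optional[Lexicons] = None,
    seed: int = 0,
) -> list[CorpusPair]:
    """Produce ``k`` (0-4) slot-substituted variants of a pair.

    Each variant applies at least one of the four substitution classes;
    the substituted surface string is replaced identically in the sentence
    and the structured side, so variants keep the pair-consistency contract
    and still parse in strict mode.
    """
    if not 0 <= k <= MAX_AUGMENT:
        raise ValueError(f"k must be in [0, {MAX_AUGMENT}], got {k}")
    if k == 0:
        return []
    lex = lexicons or default_lexicons()
    lex.validate()
    applicable = [c for c in AUGMENT_CLASSES if _augmentable_slots(pair, c)]
    if not applicable:
        raise AugmentError("pair has no augmentable slots")
    rng = np.random.default_rng(seed)
    variants = []
    for v in range(k):
        cls = applicable[int(rng.integers(len(applicable)))]
        slot_keys = _augmentable_slots(pair, cls)
        slot = slot_keys[int(rng.integers(len(slot_keys)))]
        old = pair.slots[slot]
        if old not in pair.sentence or old not in pair.structured:
            raise AugmentError(
                f"slot {slot!r} surface {old!r} missing from pair text")
        new = _replacement(cls, old, rng, lex)
        # mirror plain text replacement so slot provenance stays aligned even
        # when the old surface is a substring of another slot's surface
        slots = {key: val.replace(old, new) for key, val in pair.slots.items()}
        variants.append(
            CorpusPair(
                sentence=pair.sentence.replace(old, new),
                structured=pair.structured.replace(old, new),
                slots=slots,
                origin="augmented",
                parent_id=pair.id,
                id=f"{pair.id or 'pair'}-aug{v}",
                actions=list(pair.actions),
            )
        )
    return variants


# --------------------------------------------------------------------------
# Negative paragraphs for the classification task

_NEGATIVE_TEMPLATES = (
    # references another procedure (R3)
    "Following general procedure {letter}, the desired material was obtained "
    "from the corresponding starting materials and used without further "
    "analysis.",
    # numbered compound reference (R4)
    "Compound {num} was dissolved in the reaction medium and treated as "
    "described in the preceding paragraphs of this disclosure.",
    # too short (R1)
    "Prepared from intermediate materials.",
    # ends abruptly (R2)
    "The formulation comprises {num} mg of active ingredient blended with "
    "microcrystalline cellulose and the mixture was",
    # product euphemism without a proper name (R5)
    "The product was isolated as a white solid in {num}% purity and stored "
    "in a sealed amber vial under inert gas until use.",
    # property description with a euphemism (R5)
    "The title compound shows a melting point of {num} degrees and good "
    "stability in buffered media over several weeks of storage.",
)


def generate_negatives(
    n: int, seed: int = 0, cfg: Optional[GeneratorConfig] = None
) -> list[ParagraphRecord]:
    """Generate ``n`` paragraphs that each violate an admission rule."""
    if n < 0:
        raise ConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    letters = "ABCDEFG"
    records = []
    for i in range(n):
        template = _NEGATIVE_TEMPLATES[int(rng.integers(len(_NEGATIVE_TEMPLATES)))]
        text = template.format(
            letter=letters[int(rng.integers(len(letters)))],
            num=int(rng.integers(1, 99)),
        )
        records.append(ParagraphRecord(id=f"neg-{i:06d}", text=text, label=0))
    return records


def generate_classification_set(
    n: int,
    seed: int = 0,
    positive_fraction: float = 0.336,
    lexicons: Optional[Lexicons] = None,
    sentences_per_positive: tuple[int, int] = (2, 4),
) -> list[ParagraphRecord]:
    """A labeled paragraph set: synthesis paragraphs (1) vs negatives (0).

    The positive count is ``round(n * positive_fraction)``; records are
    shuffled deterministically.
    """
    if not (0.0 < positive_fraction < 1.0):
        raise ConfigError("positive_fraction must be in (0, 1)")
    n_pos = int(round(n * positive_fraction))
    n_neg = n - n_pos
    rng = np.random.default_rng(seed)
    pair_cfg = GeneratorConfig(
        n=n_pos * sentences_per_positive[1], seed=int(rng.integers(2**31)),
        lexicons=lexicons)
    pairs = generate_pairs(pair_cfg) if n_pos else []
    positives = []
    cursor = 0
    lo, hi = sentences_per_positive
    for i in range(n_pos):
        m = int(rng.integers(lo, hi + 1))
        chunk = pairs[cursor:cursor + m]
        cursor += m
        text = " ".join(p.sentence for p in chunk)
        positives.append(ParagraphRecord(id=f"pos-{i:06d}", text=text, label=1))
    negatives = generate_negatives(n_neg, seed=int(rng.integers(2**31)))
    records = positives + negatives
    order = rng.permutation(len(records))
    return [records[i] for i in order]


# --------------------------------------------------------------------------
# Splitting

def split(dataset: Sequence, seed: int = 0):
    """Shuffle and split into train/validation/test.

    validation = round(0.1 N), test = round(0.1 N), train = remainder —
    the rounding rule that maps N=20,199 to (16,159, 2,020, 2,020) and
    N=3,074,038 to (2,459,230, 307,404, 307,404).
    """
    n = len(dataset)
    if n < 3:
        raise SizeError(f"need at least 3 records to split, got {n}")
    n_val = round(0.1 * n)
    n_test = round(0.1 * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = order[: n - n_val - n_test]
    val_idx = order[n - n_val - n_test: n - n_test]
    test_idx = order[n - n_test:]
    pick = lambda idx: [dataset[int(i)] for i in idx]
    return pick(train_idx), pick(val_idx), pick(test_idx)


# --------------------------------------------------------------------------
# Rule-oracle converter: the template inverse

def rule_oracle_translate(sentence: str) -> str:
    """Map a template-generated sentence back to its structured string.

    Fragments that match no template become INVALIDACTION clauses carrying
    the raw fragment, mirroring the lenient parser policy.
    """
    text = sentence.strip()
    if text.endswith("."):
        text = text[:-1]
    fragments = text.split(_CONNECTIVE)
    struct_parts = []
    for fragment in fragments:
        fragment = fragment.strip()
        for template, regex in _TEMPLATE_REGEXES:
            m = regex.match(fragment)
            if m:
                struct_parts.append(template.struct.format(**m.groupdict()))
                break
        else:
            struct_parts.append(f"INVALIDACTION {fragment}")
    return "; ".join(struct_parts) + "."


# --------------------------------------------------------------------------
# Corpus IO

def write_pairs_tsv(pairs: Sequence[CorpusPair], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for p in pairs:
            writer.writerow([p.sentence, p.structured])


def read_pairs_tsv(path) -> list[CorpusPair]:
    pairs = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row:
                continue
            pairs.append(CorpusPair(sentence=row[0], structured=row[1]))
    return pairs


def write_pairs_jsonl(pairs: Sequence[CorpusPair], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(json.dumps({
                "id": p.id, "sentence": p.sentence, "structured": p.structured,
                "slots": p.slots, "origin": p.origin, "parent_id": p.parent_id,
                "actions": p.actions,
            }, ensure_ascii=False) + "\n")


def read_pairs_jsonl(path) -> list[CorpusPair]:
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            pairs.append(CorpusPair(
                sentence=rec["sentence"], structured=rec["structured"],
                slots=rec.get("slots", {}), origin=rec.get("origin", "template"),
                parent_id=rec.get("parent_id"), id=rec.get("id"),
                actions=rec.get("actions", []),
            ))
    return pairs
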