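"""Admission rules deciding whether a paragraph is a well-formed procedure.

Five rules are applied to candidate paragraphs before they enter the labeled
classification corpus:

R1  at least ``min_words`` whitespace tokens (default 10);
R2  the text must not end abruptly: it has to close with terminal
    punctuation, optionally followed by a closing quote/bracket;
R3  no references to other methods or procedures ("following general
    procedure A", "as described in", ...);
R4  no numbered compound references ("Compound 1", "INTERMEDIATE 2",
    "Example 3");
R5  product euphemisms ("title compound", "white solid", ...) are allowed
    only when a proper IUPAC-like compound name appears in the same sentence.

A paragraph is admissible iff no rule fires.  Rules are pure text heuristics:
the trained classifier (``synthaction.models``) is a separate, learned layer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ParagraphRecord",
    "RuleConfig",
    "admissible_procedure",
    "looks_iupac",
]


@dataclass
class ParagraphRecord:
    id: str
    text: str
    label: Optional[int] = None
    violations: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.text is None:
            raise ValueError("paragraph text must not be None")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


DEFAULT_REFERENCE_PHRASES = (
    "following general procedure",
    "following the general procedure",
    "as described in",
    "as described above",
    "according to the procedure",
    "according to general procedure",
    "in a manner similar to",
    "in a similar manner",
    "using the method of",
    "prepared as in",
    "by the method described",
)

# the negative lookahead keeps "Compound 1" matches from firing on numbered
# chemical names like "compound 1-benzyl-2-(chloromethyl)pyrrolidine"
DEFAULT_COMPOUND_REF_PATTERNS = (
    r"\bcompound\s+\d+[a-z]?(?![\w,.-]*[a-z(])",
    r"\bintermediate\s+\d+[a-z]?(?![\w,.-]*[a-z(])",
    r"\bexample\s+\d+[a-z]?(?![\w,.-]*[a-z(])",
)

DEFAULT_TITLE_PHRASES = (
    "title compound",
    "resultant compound",
    "desired compound",
    "desired product",
    "title product",
    "white solid",
    "yellow crystals",
    "black powder",
)

# Morphemes characteristic of systematic nomenclature.
_IUPAC_MORPHEMES = (
    "yl", "oxy", "amino", "benzo", "pyridin", "pyrrolidin", "piperidin",
    "phenyl", "methyl", "ethyl", "propyl", "butyl", "chloro", "fluoro",
    "bromo", "iodo", "nitro", "cyano", "hydroxy", "acet", "carb", "sulf",
    "amide", "amine", "azole", "indol", "furan", "thio", "ol", "one",
    "acid", "ate", "ene", "yne", "ine",
)
_LOCANT_RE = re.compile(r"(?:^|[\s(,-])\d+(?:,\d+)*-")
_BRACKET_RE = re.compile(r"\S[\[(]|[\])]\S|\(\(")


@dataclass
class RuleConfig:
    min_words: int = 10
    reference_phrases: tuple[str, ...] = DEFAULT_REFERENCE_PHRASES
    compound_ref_patterns: tuple[str, ...] = DEFAULT_COMPOUND_REF_PATTERNS
    title_phrases: tuple[str, ...] = DEFAULT_TITLE_PHRASES
    iupac_heuristic: bool = True
    iupac_min_features: int = 2

    def __post_init__(self):
        if self.min_words < 1:
            raise ValueError("min_words must be >= 1")
        self.reference_phrases = tuple(p.lower() for p in self.reference_phrases)
        self.title_phrases = tuple(p.lower() for p in self.title_phrases)


def looks_iupac(name_candidate: str, min_features: int = 2) -> bool:
    """Heuristic for 'is this span a systematic chemical name?'.

    Scores three feature classes — digit-locant punctuation ("3-", "2,3-"),
    bracket nesting inside a token, and characteristic nomenclature
    morphemes — and returns True when at least ``min_features`` fire.
    """
    span = name_candidate.strip()
    if not span:
        raise ValueError("empty candidate span")
    lowered = span.lower()
    features = 0
    if _LOCANT_RE.search(span) or re.match(r"^\d+(?:,\d+)*-", span):
        features += 1
    if _BRACKET_RE.search(span):
        features += 1
    morpheme_hits = sum(1 for m in _IUPAC_MORPHEMES if m in lowered)
    if morpheme_hits >= 2:
        features += 1
    # a dense hyphenated token ("1-benzyl-2-...") is itself nomenclature-like
    if any(tok.count("-") >= 2 and any(c.isdigit() for c in tok)
           for tok in span.split()):
        features += 1
    return features >= min_features


_TERMINAL_RE = re.compile(r"[.!?][\"'”’)\]]*$")
_SENTENCE_BREAK = re.compile(r"(?<=[.!?])\s+")


def _rule_violations(text: str, cfg: RuleConfig) -> list[str]:
    violations = []
    if len(text.split()) < cfg.min_words:
        violations.append("R1")
    if not _TERMINAL_RE.search(text.rstrip()):
        violations.append("R2")
    lowered = text.lower()
    if any(phrase in lowered for phrase in cfg.reference_phrases):
        violations.append("R3")
    if any(re.search(pat, text, flags=re.IGNORECASE)
           for pat in cfg.compound_ref_patterns):
        violations.append("R4")
    if cfg.iupac_heuristic:
        for sentence in _SENTENCE_BREAK.split(text):
            sl = sentence.lower()
            if any(phrase in sl for phrase in cfg.title_phrases):
                if not looks_iupac(sentence, cfg.iupac_min_features):
                    violations.append("R5")
                    break
    return violations


def admissible_procedure(
    p: ParagraphRecord, cfg: RuleConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply rules R1-R5; returns (decision, violation codes).

    The decision is True iff the violation list is empty.  The record's
    ``violations`` field is updated in place as an annotation.
    """
    cfg = cfg or RuleConfig()
    violations = _rule_violations(p.text, cfg)
    p.violations = list(violations)
    return (not violations), violations
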