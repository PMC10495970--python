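"""End-to-end orchestration: paragraphs → classify → split → translate →
extract → tabular reaction records.

The pipeline mirrors the production path from raw procedure paragraphs to a
structured reaction dataset:

1. admission/classification — either the rule filter (R1–R5), a trained
   classifier, or both;
2. deduplication by normalized paragraph text;
3. sentence splitting (rule-based, abbreviation-aware);
4. sentence-to-structured conversion — a trained seq2seq model or the
   deterministic rule oracle (the synthetic-template inverse), which gives a
   converter-independent test path;
5. recomposition of sentence-level clause lists into one action sequence;
6. reactant/product extraction and name→SMILES resolution.

Paragraphs whose structured output fails strict parsing are quarantined
into an errors list rather than silently dropped; translations containing
INVALIDACTION or FOLLOWOTHERPROCEDURE clauses are excluded by default, as
such content is either not a real operation or points outside the text.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from . import actionlang
from .actionlang import ActionType
from .errors import ConfigError, EmptyInput
from .extract import (NameDictionary, ProcedureRecord, collect_product,
                      collect_reactants, default_stoplist, to_smiles)
from .filters import ParagraphRecord, RuleConfig, admissible_procedure
from .synthcorpus import rule_oracle_translate

__all__ = [
    "PipelineConfig", "SentenceSplit", "split_sentences", "dedupe",
    "run", "RunReport",
]

# Abbreviations that must not terminate a sentence even when followed by
# whitespace and an uppercase letter.
DEFAULT_ABBREVIATIONS = (
    "e.g", "i.e", "approx", "ca", "cf", "vs", "etc", "wt", "vol", "no",
    "eq", "equiv", "fig", "ref", "dr", "mr", "mrs", "prof", "min", "max",
    "temp", "anhyd", "sat", "aq", "conc", "dil", "mp", "bp",
)


@dataclass(frozen=True)
class SentenceSplit:
    """Ordered, non-overlapping half-open character spans over a paragraph."""

    text: str
    spans: tuple[tuple[int, int], ...]

    @property
    def sentences(self) -> list[str]:
        return [self.text[a:b].strip() for a, b in self.spans]


_BOUNDARY = re.compile(r"[.!?][\"')\]]*\s+(?=[A-Z0-9(])")


def split_sentences(
    paragraph: str,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> SentenceSplit:
    """Rule-based sentence boundary detection.

    A boundary is a sentence-terminal punctuation mark followed by
    whitespace and an uppercase letter, digit or opening parenthesis —
    unless the token before the period is a known abbreviation, or the
    position is inside parentheses.  Temperature notations such as "°C."
    therefore split exactly when followed by an uppercase continuation.
    """
    if not paragraph or not paragraph.strip():
        raise EmptyInput("paragraph is empty")
    abbrev = {a.lower().rstrip(".") for a in abbreviations}
    boundaries = [0]
    depth = 0
    for i, ch in enumerate(paragraph):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch not in ".!?" or depth > 0:
            continue
        m = _BOUNDARY.match(paragraph, i)
        if not m:
            continue
        if ch == ".":
            before = paragraph[boundaries[-1]:i]
            last = before.split()[-1] if before.split() else ""
            token = last.rstrip(".").lstrip("(\"'").lower()
            if token in abbrev:
                continue
        boundaries.append(m.end())
    spans = []
    for start, end in zip(boundaries, boundaries[1:] + [len(paragraph)]):
        chunk = paragraph[start:end]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            spans.append((start + lead, end - trail))
    return SentenceSplit(text=paragraph, spans=tuple(spans))


def _dedupe_key(text: str) -> str:
    normalized = re.sub(r"\s+", " ", text).strip().lower()
    return hashlib.sha1(normalized.encode("utf-8")).hexdigest()


def dedupe(records: Sequence[ParagraphRecord]) -> list[ParagraphRecord]:
    """Keep the first occurrence of each normalized paragraph."""
    seen: set[str] = set()
    kept = []
    for rec in records:
        key = _dedupe_key(rec.text)
        if key not in seen:
            seen.add(key)
            kept.append(rec)
    return kept


@dataclass
class PipelineConfig:
    converter: str = "rule_oracle"  # "rule_oracle" or "model"
    use_rule_filter: bool = True
    classifier: Optional[object] = None  # TrainedModel, for converter stages
    seq2seq: Optional[object] = None  # TrainedModel when converter == "model"
    classifier_threshold: float = 0.5
    rule_config: RuleConfig = field(default_factory=RuleConfig)
    dictionary: Optional[NameDictionary] = None
    stoplist: Optional[frozenset] = None
    exclude_invalid: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.converter not in ("rule_oracle", "model"):
            raise ConfigError("converter must be 'rule_oracle' or 'model'")
        if self.converter == "model" and self.seq2seq is None:
            raise ConfigError("converter 'model' requires a seq2seq model")
        if not self.use_rule_filter and self.classifier is None:
            raise ConfigError(
                "need the rule filter and/or a trained classifier")


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "counts": self.counts}, indent=2)


_EXCLUDED_ACTIONS = {ActionType.InvalidAction, ActionType.FollowOtherProcedure}


def _make_translator(cfg: PipelineConfig) -> Callable[[list[str]], list[str]]:
    if cfg.converter == "rule_oracle":
        return lambda sentences: [rule_oracle_translate(s) for s in sentences]
    from .models import translate_batch
    return lambda sentences: translate_batch(cfg.seq2seq, sentences)


def run(
    records: Sequence[ParagraphRecord],
    cfg: Optional[PipelineConfig] = None,
) -> tuple[list[ProcedureRecord], list[dict], RunReport]:
    """Process paragraphs end to end.

    Returns (procedure records, quarantined errors, stage-count report).
    Stage counts are monotone non-increasing from input to output, and the
    whole run is deterministic for a fixed config.
    """
    cfg = cfg or PipelineConfig()
    cfg.validate()
    dictionary = cfg.dictionary or NameDictionary.bundled()
    stoplist = cfg.stoplist if cfg.stoplist is not None else default_stoplist()

    counts = {"input": len(records)}
    deduped = dedupe(records)
    counts["after_dedupe"] = len(deduped)

    admitted = []
    for rec in deduped:
        if cfg.use_rule_filter:
            ok, _ = admissible_procedure(rec, cfg.rule_config)
            if not ok:
                continue
        admitted.append(rec)
    if cfg.classifier is not None:
        from .models import predict_proba
        probs = predict_proba(cfg.classifier, [r.text for r in admitted])
        admitted = [r for r, p in zip(admitted, probs)
                    if p >= cfg.classifier_threshold]
    counts["after_admission"] = len(admitted)

    translator = _make_translator(cfg)
    results: list[ProcedureRecord] = []
    errors: list[dict] = []
    n_excluded = 0
    for rec in admitted:
        sentences = split_sentences(rec.text).sentences
        structured_parts = translator(sentences)
        # join sentence-level clause lists into one paragraph-level sequence
        merged = "; ".join(part.rstrip(".") for part in structured_parts if
                           part.strip()) + "."
        try:
            seq = actionlang.parse_structured(merged, mode="strict")
        except Exception as exc:  # quarantine, never drop silently
            errors.append({"id": rec.id, "stage": "parse", "error": str(exc),
                           "structured": merged})
            continue
        if cfg.exclude_invalid and any(
                c.action in _EXCLUDED_ACTIONS for c in seq.clauses):
            n_excluded += 1
            continue
        reactants = collect_reactants(seq, stoplist)
        product = collect_product(seq)
        results.append(ProcedureRecord(
            source_id=rec.id,
            paragraph=rec.text,
            structured=merged,
            reactants=reactants,
            product=product,
            reactant_smiles=to_smiles(reactants, dictionary),
            product_smiles=to_smiles([product] if product else [], dictionary),
        ))
    counts["excluded_invalid"] = n_excluded
    counts["quarantined"] = len(errors)
    counts["records"] = len(results)
    return results, errors, RunReport(counts=counts, seed=cfg.seed)


def write_records_jsonl(records: Sequence[ProcedureRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps({
                "source_id": r.source_id, "paragraph": r.paragraph,
                "structured": r.structured, "reactants": r.reactants,
                "product": r.product,
                "reactant_smiles": r.reactant_smiles,
                "product_smiles": r.product_smiles,
            }, ensure_ascii=False) + "\n")


def write_records_tsv(records: Sequence[ProcedureRecord], path) -> None:
    import csv
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source_id", "paragraph", "structured", "reactants",
                        "product", "reactant_smiles", "product_smiles"])
        for r in records:
            writer.writerow([
                r.source_id, r.paragraph, r.structured,
                "|".join(r.reactants), r.product or "",
                "|".join(s or "?" for _, s in r.reactant_smiles),
                "|".join(s or "?" for _, s in r.product_smiles),
            ])
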