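"""The structured-action language: types, grammar, parser, serializer.

A synthesis procedure sentence is summarized as a sequence of clauses, each
starting with one of 28 action keywords (ADD, STIR, FILTER, ...) followed by
typed parameters: chemicals with optional amounts, a temperature, a duration,
a kept phase (filtration / layer collection), or a purification solvent
system. Clauses are joined with "; " and the sequence ends with a period, e.g.

    MAKESOLUTION with benzoic acid (200 mg) and tetrahydrofuran (THF) (10 mL);
    ADD SLN; ADD EDC (374 mg); STIR at 25 °C for 2 h.

``SLN`` is a reserved token referencing the solution created by the preceding
MAKESOLUTION clause and is never treated as a chemical name.

The normative grammar is documented in ``docs/grammar.md``; this module is its
reference implementation, with the round-trip guarantee

    serialize(parse_structured(s)) == normalize(s)

for every grammar-conforming string ``s``.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import EmptyInput, InvalidSequence, MalformedClause, UnknownAction

__all__ = [
    "ActionType",
    "ChemicalMention",
    "ActionClause",
    "ActionSequence",
    "Violation",
    "parse_structured",
    "serialize",
    "validate",
    "normalize",
    "SLN_TOKEN",
]

SLN_TOKEN = "SLN"


class ActionType(enum.Enum):
    """The 28 action types of the structured procedure language."""

    Add = "ADD"
    CollectLayer = "COLLECTLAYER"
    Concentrate = "CONCENTRATE"
    Degas = "DEGAS"
    DrySolid = "DRYSOLID"
    DrySolution = "DRYSOLUTION"
    Extract = "EXTRACT"
    Filter = "FILTER"
    FollowOtherProcedure = "FOLLOWOTHERPROCEDURE"
    MakeSolution = "MAKESOLUTION"
    Microwave = "MICROWAVE"
    OtherLanguage = "OTHERLANGUAGE"
    Partition = "PARTITION"
    PH = "PH"
    PhaseSeparation = "PHASESEPARATION"
    InvalidAction = "INVALIDACTION"
    Purify = "PURIFY"
    Quench = "QUENCH"
    Recrystallize = "RECRYSTALLIZE"
    NoAction = "NOACTION"
    Reflux = "REFLUX"
    SetTemperature = "SETTEMPERATURE"
    Sonicate = "SONICATE"
    Stir = "STIR"
    Triturate = "TRITURATE"
    Wait = "WAIT"
    Wash = "WASH"
    Yield = "YIELD"

    @property
    def surface(self) -> str:
        """Canonical uppercase keyword used in serialized text."""
        return self.value


_BY_SURFACE = {a.value: a for a in ActionType}

# Payload families.  The grammar groups the 28 actions by the shape of the
# text that may follow the keyword; every clause additionally accepts trailing
# "at <temperature>" and "for <duration>" modifiers.
BARE_ITEM_ACTIONS = frozenset({ActionType.Add, ActionType.Yield})
WITH_ITEMS_ACTIONS = frozenset(
    {
        ActionType.MakeSolution,
        ActionType.Quench,
        ActionType.Wash,
        ActionType.Extract,
        ActionType.Partition,
        ActionType.Triturate,
        ActionType.Recrystallize,
        ActionType.Degas,
    }
)
OVER_ITEM_ACTIONS = frozenset({ActionType.DrySolution})
KEEP_ACTIONS = frozenset({ActionType.Filter, ActionType.CollectLayer})
FREE_TEXT_ACTIONS = frozenset(
    {
        ActionType.PH,
        ActionType.FollowOtherProcedure,
        ActionType.InvalidAction,
        ActionType.NoAction,
        ActionType.OtherLanguage,
        ActionType.PhaseSeparation,
    }
)
BARE_ACTIONS = frozenset(
    {
        ActionType.Concentrate,
        ActionType.DrySolid,
        ActionType.Microwave,
        ActionType.Reflux,
        ActionType.Sonicate,
        ActionType.Stir,
        ActionType.Wait,
    }
)
# SetTemperature carries its temperature as the direct payload.

KEEP_PHASES = {
    ActionType.Filter: ("precipitate", "filtrate"),
    ActionType.CollectLayer: ("organic", "aqueous"),
}


@dataclass
class ChemicalMention:
    """A chemical name with an optional verbatim amount, or an SLN reference."""

    name: str
    amount: Optional[str] = None
    is_solution_ref: bool = False

    def render(self) -> str:
        if self.is_solution_ref:
            return SLN_TOKEN
        return f"{self.name} ({self.amount})" if self.amount else self.name


@dataclass
class ActionClause:
    action: ActionType
    chemicals: list[ChemicalMention] = field(default_factory=list)
    temperature: Optional[str] = None
    duration: Optional[str] = None
    keep_phase: Optional[str] = None
    purify_solvents: list[str] = field(default_factory=list)
    purify_ratio: Optional[str] = None
    free_params: Optional[str] = None


@dataclass
class ActionSequence:
    clauses: list[ActionClause] = field(default_factory=list)
    source_sentence: Optional[str] = None

    @property
    def action_types(self) -> list[ActionType]:
        return [c.action for c in self.clauses]


@dataclass(frozen=True)
class Violation:
    clause: int  # -1 for sequence-level violations
    rule: str
    message: str


def _collapse_ws(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


def normalize(text: str) -> str:
    """Canonical surface form: collapsed whitespace, '; ' separators, final '.'."""
    text = _collapse_ws(text)
    text = text.rstrip(". ").rstrip()
    segments = [seg.strip() for seg in text.split(";")]
    segments = [seg for seg in segments if seg]
    return "; ".join(segments) + "."


def _split_top_level(text: str, sep: str) -> list[str]:
    """Split on ``sep`` only where parenthesis depth is zero."""
    parts, depth, start = [], 0, 0
    i, n, w = 0, len(text), len(sep)
    while i < n:
        ch = text[i]
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif depth == 0 and text.startswith(sep, i):
            parts.append(text[start:i])
            i += w
            start = i
            continue
        i += 1
    parts.append(text[start:])
    return parts


# a quantity parenthetical has a digit and at least two tokens ("200 mg",
# "10 mL"); bare "(0)" or "(THF)" stay part of the chemical name
_AMOUNT_TAIL = re.compile(
    r"^(?P<name>.*\S)\s+\((?P<amount>[^()]*\d[^()]*\s[^()]+)\)$")


def _parse_item(text: str) -> ChemicalMention:
    text = text.strip()
    if not text:
        raise MalformedClause("empty chemical item")
    if text == SLN_TOKEN:
        return ChemicalMention(name="", is_solution_ref=True)
    m = _AMOUNT_TAIL.match(text)
    if m:
        return ChemicalMention(name=m.group("name"), amount=m.group("amount"))
    return ChemicalMention(name=text)


def _parse_items(text: str) -> list[ChemicalMention]:
    return [_parse_item(part) for part in _split_top_level(text, " and ")]


def _strip_modifiers(payload: str) -> tuple[str, Optional[str], Optional[str]]:
    """Pull trailing 'for <duration>' then 'at <temperature>' off a payload.

    The payload is padded with a leading space so a clause whose payload IS
    the modifier ("WAIT for 2 h") is handled by the same top-level split.
    """
    duration = temperature = None
    parts = _split_top_level(" " + payload, " for ")
    if len(parts) > 1:
        duration = parts[-1].strip() or None
        payload = " for ".join(parts[:-1])
    parts = _split_top_level(" " + payload.strip(), " at ")
    if len(parts) > 1:
        temperature = parts[-1].strip() or None
        payload = " at ".join(parts[:-1])
    return payload.strip(), temperature, duration


def _parse_clause(segment: str, strict: bool) -> ActionClause:
    segment = segment.strip()
    m = re.match(r"^([A-Za-z]+)\s*(.*)$", segment, flags=re.DOTALL)
    head, payload = (m.group(1), m.group(2)) if m else (segment, "")
    action = _BY_SURFACE.get(head.upper())
    if action is None:
        if strict:
            raise UnknownAction(f"unknown action keyword: {head!r}")
        return ActionClause(action=ActionType.InvalidAction, free_params=segment)
    payload = payload.strip()
    try:
        return _parse_payload(action, payload)
    except MalformedClause:
        if strict:
            raise
        return ActionClause(action=ActionType.InvalidAction, free_params=segment)


def _parse_payload(action: ActionType, payload: str) -> ActionClause:
    clause = ActionClause(action=action)
    if action is ActionType.SetTemperature:
        # the temperature IS the payload ("SETTEMPERATURE 0 °C")
        body, temp, dur = _strip_modifiers(payload)
        clause.temperature = body or temp
        clause.duration = dur
        if not clause.temperature:
            raise MalformedClause("SETTEMPERATURE requires a temperature")
        return clause
    if action is ActionType.Purify:
        if not payload.startswith(":"):
            if payload:
                raise MalformedClause("PURIFY payload must start with ':'")
            return clause
        body, temp, dur = _strip_modifiers(payload[1:])
        clause.temperature, clause.duration = temp, dur
        m = re.match(r"^(?P<solv>.*?)\s*\((?P<ratio>\d+(?::\d+)+)\)$", body)
        if m:
            clause.purify_ratio = m.group("ratio")
            body = m.group("solv")
        solvents = [s.strip() for s in body.split(":")]
        if any(not s for s in solvents):
            raise MalformedClause("PURIFY has an empty solvent entry")
        clause.purify_solvents = solvents
        return clause

    body, clause.temperature, clause.duration = _strip_modifiers(payload)

    if action in KEEP_ACTIONS:
        if body:
            m = re.match(r"^keep\s+(\S+)$", body, flags=re.IGNORECASE)
            if not m or m.group(1).lower() not in KEEP_PHASES[action]:
                raise MalformedClause(
                    f"{action.surface} accepts only 'keep "
                    f"{'|'.join(KEEP_PHASES[action])}'"
                )
            clause.keep_phase = m.group(1).lower()
        return clause
    if action in BARE_ITEM_ACTIONS:
        if not body:
            raise MalformedClause(f"{action.surface} requires a chemical item")
        if action is ActionType.Yield:
            clause.chemicals = [_parse_item(body)]
        else:
            clause.chemicals = _parse_items(body)
        return clause
    if action in WITH_ITEMS_ACTIONS:
        if body:
            m = re.match(r"^with\s+(.*)$", body, flags=re.IGNORECASE)
            if not m:
                raise MalformedClause(f"{action.surface} payload must start with 'with'")
            clause.chemicals = _parse_items(m.group(1))
        return clause
    if action in OVER_ITEM_ACTIONS:
        if body:
            m = re.match(r"^over\s+(.*)$", body, flags=re.IGNORECASE)
            if not m:
                raise MalformedClause(f"{action.surface} payload must start with 'over'")
            clause.chemicals = [_parse_item(m.group(1))]
        return clause
    if action in FREE_TEXT_ACTIONS:
        clause.free_params = body or None
        return clause
    # bare actions: no residual payload allowed
    if body:
        raise MalformedClause(f"{action.surface} takes no parameters, got {body!r}")
    return clause


def parse_structured(text: str, mode: str = "strict") -> ActionSequence:
    """Parse a structured-format string into an :class:`ActionSequence`.

    ``mode='strict'`` rejects unknown keywords and malformed payloads;
    ``mode='lenient'`` maps offending segments to ``InvalidAction`` clauses
    with the raw text preserved in ``free_params``.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    stripped = text.strip() if text else ""
    if not stripped:
        raise EmptyInput("structured text is empty")
    stripped = _collapse_ws(stripped).rstrip(".").rstrip()
    segments = [seg.strip() for seg in stripped.split(";") if seg.strip()]
    if not segments:
        raise EmptyInput("structured text has no clauses")
    clauses = [_parse_clause(seg, strict=(mode == "strict")) for seg in segments]
    return ActionSequence(clauses=clauses)


def _serialize_clause(clause: ActionClause) -> str:
    action = clause.action
    parts = [action.surface]
    if action is ActionType.SetTemperature:
        parts.append(clause.temperature or "")
        out = " ".join(p for p in parts if p)
        if clause.duration:
            out += f" for {clause.duration}"
        return out
    if action is ActionType.Purify:
        solv = ":".join(clause.purify_solvents)
        if clause.purify_ratio:
            solv += f" ({clause.purify_ratio})"
        out = f"{action.surface}: {solv}" if solv else action.surface
    elif action in KEEP_ACTIONS:
        out = action.surface
        if clause.keep_phase:
            out += f" keep {clause.keep_phase}"
    elif action in BARE_ITEM_ACTIONS:
        out = f"{action.surface} " + " and ".join(c.render() for c in clause.chemicals)
    elif action in WITH_ITEMS_ACTIONS:
        out = action.surface
        if clause.chemicals:
            out += " with " + " and ".join(c.render() for c in clause.chemicals)
    elif action in OVER_ITEM_ACTIONS:
        out = action.surface
        if clause.chemicals:
            out += f" over {clause.chemicals[0].render()}"
    elif action in FREE_TEXT_ACTIONS:
        out = action.surface
        if clause.free_params:
            out += f" {clause.free_params}"
    else:
        out = action.surface
    if clause.temperature and action is not ActionType.SetTemperature:
        out += f" at {clause.temperature}"
    if clause.duration:
        out += f" for {clause.duration}"
    return out


def serialize(seq: ActionSequence) -> str:
    """Render an :class:`ActionSequence` back to its canonical surface form."""
    violations = validate(seq)
    if violations:
        raise InvalidSequence("; ".join(v.message for v in violations))
    return "; ".join(_serialize_clause(c) for c in seq.clauses) + "."


def validate(seq: ActionSequence) -> list[Violation]:
    """Check type invariants; returns an empty list iff the sequence is valid."""
    violations: list[Violation] = []
    if not seq.clauses:
        violations.append(Violation(-1, "empty_sequence", "sequence has no clauses"))
        return violations
    for i, clause in enumerate(seq.clauses):
        a = clause.action
        if clause.keep_phase is not None:
            if a not in KEEP_ACTIONS:
                violations.append(
                    Violation(i, "keep_scope", f"clause {i}: keep_phase only valid "
                              "for FILTER/COLLECTLAYER")
                )
            elif clause.keep_phase not in KEEP_PHASES[a]:
                violations.append(
                    Violation(i, "keep_value", f"clause {i}: keep_phase "
                              f"{clause.keep_phase!r} not allowed for {a.surface}")
                )
        if (clause.purify_solvents or clause.purify_ratio) and a is not ActionType.Purify:
            violations.append(
                Violation(i, "purify_scope",
                          f"clause {i}: purify solvents only valid for PURIFY")
            )
        for chem in clause.chemicals:
            if not chem.is_solution_ref and not chem.name:
                violations.append(
                    Violation(i, "empty_name", f"clause {i}: empty chemical name")
                )
        if clause.chemicals and a in (BARE_ACTIONS | FREE_TEXT_ACTIONS
                                      | {ActionType.SetTemperature}):
            violations.append(
                Violation(i, "bare_chemicals",
                          f"clause {i}: {a.surface} takes no chemicals")
            )
        if a in BARE_ITEM_ACTIONS and not clause.chemicals:
            violations.append(
                Violation(i, "missing_item",
                          f"clause {i}: {a.surface} requires a chemical item")
            )
    return violations
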