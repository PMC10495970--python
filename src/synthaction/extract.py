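"""Reactant/product extraction and name→SMILES resolution.

Once a procedure paragraph is in structured form, the tabular reaction
dataset is derived from it by simple, auditable rules: chemicals introduced
by ADD and MAKESOLUTION clauses are the reactant candidates, the chemical of
the first YIELD clause is the product, and common solvents are removed from
the reactant list through a configurable stoplist (they appear in ADD /
MAKESOLUTION steps only as the synthesis medium).  Names are mapped to
SMILES through a local two-column TSV dictionary; unresolved names are kept
and flagged, never dropped.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .actionlang import ActionSequence, ActionType
from .errors import DictError

__all__ = [
    "ProcedureRecord",
    "NameDictionary",
    "load_stoplist",
    "default_stoplist",
    "collect_reactants",
    "collect_product",
    "to_smiles",
]

logger = logging.getLogger(__name__)

UNRESOLVED = None  # resolution status marker in (name, smiles) tuples


@dataclass
class ProcedureRecord:
    """One row of the final reaction dataset."""

    source_id: str
    paragraph: str
    structured: str
    reactants: list[str] = field(default_factory=list)
    product: Optional[str] = None
    reactant_smiles: list[tuple[str, Optional[str]]] = field(default_factory=list)
    product_smiles: list[tuple[str, Optional[str]]] = field(default_factory=list)


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip().lower()


_PAREN_TAIL = re.compile(r"\s*\(([^()]*)\)\s*$")


def _strip_abbreviations(name: str) -> str:
    """Drop trailing non-quantity parentheticals: 'tetrahydrofuran (THF)'
    → 'tetrahydrofuran'.  Quantity-looking groups are left alone."""
    while True:
        m = _PAREN_TAIL.search(name)
        if not m or any(c.isdigit() for c in m.group(1)):
            return name
        name = name[: m.start()].rstrip()


class NameDictionary:
    """Chemical name → SMILES lookup backed by a two-column TSV file.

    Lookups are case-insensitive and whitespace-normalized by default, which
    is the policy that resolves dictionary entries regardless of the
    capitalization used in patent prose.
    """

    def __init__(self, entries: dict[str, str], case_sensitive: bool = False):
        self.case_sensitive = case_sensitive
        self.entries: dict[str, str] = {}
        for name, smiles in entries.items():
            if not smiles or not smiles.strip():
                raise DictError(f"empty SMILES for name {name!r}")
            self.entries[self._key(name)] = smiles.strip()

    def _key(self, name: str) -> str:
        name = re.sub(r"\s+", " ", name).strip()
        return name if self.case_sensitive else name.lower()

    def lookup(self, name: str) -> Optional[str]:
        direct = self.entries.get(self._key(name))
        if direct is not None:
            return direct
        return self.entries.get(self._key(_strip_abbreviations(name)))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_tsv(cls, path, case_sensitive: bool = False) -> "NameDictionary":
        entries: dict[str, str] = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 2:
                    raise DictError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, "
                        f"got {len(row)}")
                entries[row[0]] = row[1]
        return cls(entries, case_sensitive=case_sensitive)

    @classmethod
    def bundled(cls) -> "NameDictionary":
        text = resources.files("synthaction.data").joinpath(
            "dictionary.tsv").read_text("utf-8")
        entries = {}
        for line in text.splitlines():
            if line.strip():
                name, smiles = line.split("\t")
                entries[name] = smiles
        return cls(entries)


def load_stoplist(path) -> frozenset[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return frozenset(
            _normalize_name(line) for line in fh if line.strip())


def default_stoplist() -> frozenset[str]:
    """Common solvents removed from reactant lists (data/stoplist.txt)."""
    text = resources.files("synthaction.data").joinpath(
        "stoplist.txt").read_text("utf-8")
    return frozenset(
        _normalize_name(line) for line in text.splitlines() if line.strip())


def _in_stoplist(name: str, stoplist: frozenset[str]) -> bool:
    if _normalize_name(name) in stoplist:
        return True
    return _normalize_name(_strip_abbreviations(name)) in stoplist


def collect_reactants(
    seq: ActionSequence, stoplist: Iterable[str] = ()
) -> list[str]:
    """Chemical names from ADD and MAKESOLUTION clauses, in order.

    SLN back-references are skipped, duplicates collapse to the first
    occurrence, and stoplist members (case-insensitive; trailing
    abbreviation parentheticals ignored) are removed.
    """
    stop = frozenset(_normalize_name(s) for s in stoplist)
    seen: set[str] = set()
    names: list[str] = []
    for clause in seq.clauses:
        if clause.action not in (ActionType.Add, ActionType.MakeSolution):
            continue
        for chem in clause.chemicals:
            if chem.is_solution_ref:
                continue
            key = _normalize_name(chem.name)
            if key in seen or _in_stoplist(chem.name, stop):
                continue
            seen.add(key)
            names.append(chem.name)
    return names


def collect_product(seq: ActionSequence) -> Optional[str]:
    """Name in the first YIELD clause; None when the sequence has no YIELD."""
    found = None
    for clause in seq.clauses:
        if clause.action is ActionType.Yield and clause.chemicals:
            if found is None:
                found = clause.chemicals[0].name
            else:
                logger.warning(
                    "multiple YIELD clauses; keeping the first product %r",
                    found)
                break
    return found


def to_smiles(
    names: Iterable[str], dictionary: NameDictionary
) -> list[tuple[str, Optional[str]]]:
    """Resolve each name to (name, smiles); unresolved names get None.

    The output has exactly one entry per input name, in order.
    """
    return [(name, dictionary.lookup(name)) for name in names]
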