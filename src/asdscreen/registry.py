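"""Item registry for the 120-item school-age CBCL problem list.

The registry maps canonical item identifiers (1..120; the eight 56a-56h
sub-items occupy 113..120) to their syndrome-subscale assignment and to
membership flags for every screening subscale handled by this package:
the three ASD-related syndrome subscales (Withdrawn/Depressed, Thought
Problems, Social Problems), their combinations (ASD profile, WTP), the two
previously published item-level ASD subscales (Ooi, So), the two subscales
this pipeline constructs (DataDriven, ClinicianExpert), and the DSM-oriented
comparison subscales (Affective, Anxiety, ADH, ODD, Conduct — transcribed
from the standard published assignments).

Item wording is proprietary; items outside the published subscale tables
ship with an empty label.  All set algebra (overlap counts, composition by
syndrome) operates on item identifiers.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "SYNDROMES",
    "ItemDefinition",
    "SubscaleDefinition",
    "RegistryError",
    "load_registry",
    "get_subscale",
    "item_overlap",
    "composition_by_syndrome",
]

#: Valid syndrome-subscale assignments (Table-style superscripts a-g plus
#: the remaining syndrome scales and "none" for unlisted items).
SYNDROMES = (
    "WithdrawnDepressed",
    "ThoughtProblems",
    "SocialProblems",
    "AttentionProblems",
    "AnxiousDepressed",
    "AggressiveBehavior",
    "RuleBreaking",
    "SomaticComplaints",
    "OtherProblems",
    "none",
)

N_ITEMS = 120


class RegistryError(ValueError):
    """Raised when a registry file is malformed or violates an invariant."""


@dataclass(frozen=True)
class ItemDefinition:
    """One inventory item: identifier, short label (may be empty), syndrome."""

    item_id: int
    label: str
    syndrome: str


@dataclass(frozen=True)
class SubscaleDefinition:
    """A named subscale: a set of item identifiers."""

    name: str
    item_ids: frozenset[int]

    def __len__(self) -> int:  # convenience: len(subscale)
        return len(self.item_ids)


def _packaged_registry_path() -> Path:
    return Path(resources.files("asdscreen").joinpath("data/registry.csv"))


def load_registry(
    path: str | Path | None = None,
) -> tuple[list[ItemDefinition], list[SubscaleDefinition]]:
    """Read a registry file and return validated items and subscales.

    Parameters
    ----------
    path:
        CSV file with header ``item_id,label,syndrome,<subscale>,...`` where
        each subscale column holds 0/1 membership flags.  ``None`` loads the
        packaged registry transcribed from the published subscale tables.

    Raises
    ------
    RegistryError
        On unparseable rows (the error names the offending line), duplicate
        item identifiers, identifiers outside 1..120, unknown syndrome codes,
        or violated union invariants (ASDProfile, WTP).
    """
    src = Path(path) if path is not None else _packaged_registry_path()
    items: list[ItemDefinition] = []
    members: dict[str, set[int]] = {}
    seen: set[int] = set()
    with open(src, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise RegistryError(f"{src}: empty registry file") from None
        if header[:3] != ["item_id", "label", "syndrome"]:
            raise RegistryError(
                f"{src}: line 1: header must start with item_id,label,syndrome"
            )
        subscale_names = header[3:]
        members = {name: set() for name in subscale_names}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise RegistryError(
                    f"{src}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                item_id = int(row[0])
            except ValueError:
                raise RegistryError(
                    f"{src}: line {lineno}: item_id {row[0]!r} is not an integer"
                ) from None
            if not 1 <= item_id <= N_ITEMS:
                raise RegistryError(
                    f"{src}: line {lineno}: item_id {item_id} outside 1..{N_ITEMS}"
                )
            if item_id in seen:
                raise RegistryError(
                    f"{src}: line {lineno}: duplicate item_id {item_id}"
                )
            seen.add(item_id)
            syndrome = row[2].strip() or "none"
            if syndrome not in SYNDROMES:
                raise RegistryError(
                    f"{src}: line {lineno}: unknown syndrome {syndrome!r}"
                )
            for name, flag in zip(subscale_names, row[3:]):
                if flag.strip() not in ("0", "1"):
                    raise RegistryError(
                        f"{src}: line {lineno}: membership flag for {name!r} "
                        f"must be 0 or 1, got {flag!r}"
                    )
                if flag.strip() == "1":
                    members[name].add(item_id)
            items.append(ItemDefinition(item_id, row[1], syndrome))
    subscales = [
        SubscaleDefinition(name, frozenset(ids)) for name, ids in members.items()
    ]
    _validate_unions(src, {s.name: s.item_ids for s in subscales})
    return items, subscales


def _validate_unions(src, members: Mapping[str, frozenset[int]]) -> None:
    """ASDProfile and WTP, when present, must equal their defining unions."""
    have = members.keys()
    base = {"WithdrawnDepressed", "ThoughtProblems", "SocialProblems"}
    if "ASDProfile" in have and base <= have:
        union = members["WithdrawnDepressed"] | members["ThoughtProblems"] | members["SocialProblems"]
        if members["ASDProfile"] != union:
            raise RegistryError(
                f"{src}: ASDProfile must equal the union of the Withdrawn/"
                "Depressed, Thought Problems and Social Problems subscales"
            )
    if "WTP" in have and {"WithdrawnDepressed", "ThoughtProblems"} <= have:
        union = members["WithdrawnDepressed"] | members["ThoughtProblems"]
        if members["WTP"] != union:
            raise RegistryError(
                f"{src}: WTP must equal the union of the Withdrawn/Depressed "
                "and Thought Problems subscales"
            )


def get_subscale(
    subscales: Iterable[SubscaleDefinition], name: str
) -> SubscaleDefinition:
    """Return the subscale with the given name, or raise ``KeyError``."""
    for s in subscales:
        if s.name == name:
            return s
    raise KeyError(f"no subscale named {name!r}")


def item_overlap(a: SubscaleDefinition, b: SubscaleDefinition) -> int:
    """Number of items shared by two subscales (symmetric)."""
    return len(a.item_ids & b.item_ids)


def composition_by_syndrome(
    s: SubscaleDefinition, items: Iterable[ItemDefinition]
) -> dict[str, int]:
    """Count a subscale's items per syndrome assignment.

    Items whose syndrome is ``"none"`` are counted under ``"none"``; the
    counts always sum to ``len(s)``.
    """
    syndrome_of = {it.item_id: it.syndrome for it in items}
    counts: dict[str, int] = {}
    for item_id in s.item_ids:
        syn = syndrome_of.get(item_id, "none")
        counts[syn] = counts.get(syn, 0) + 1
    return counts
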