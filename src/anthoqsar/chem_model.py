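"""Anthocyanin compound registry and tautomeric structural forms.

Anthocyanidins and their glycosides (anthocyanins) share a flavylium
skeleton whose variable decoration is captured by four substituent slots:

* ``r1``/``r2`` — the B-ring 3'- and 5'-positions, each H, OH or OCH3;
* ``r3``/``r4`` — the 3- and 5-positions, each a free hydroxyl or a
  glycoside (glucoside, galactoside, arabinoside, rutinoside,
  sambubioside, coumaroyl-sambubioside).

Positions 7 and 4' carry constitutive hydroxyls in this compound class.
Depending on pH the chromophore interconverts between six structural
forms: the flavylium cation (FC), three quinoidal bases produced by
deprotonation of the 4'-, 5- or 7-hydroxyl (QB4', QB5, QB7), the
hydrated carbinol pseudobase (CP) and the ring-opened chalcone (Ch).
A quinoidal base can only exist when its deprotonation site carries a
free hydroxyl, so 5-glycosylated compounds lack the QB5 form.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Union

__all__ = [
    "Compound",
    "StructuralForm",
    "SubstituentError",
    "RegistryError",
    "GLYCOSIDES",
    "count_hydroxyls",
    "available_forms",
    "hydroxyl_positions",
    "load_registry",
]


class SubstituentError(ValueError):
    """An unknown substituent code, reported with the offending slot."""


class RegistryError(ValueError):
    """A malformed registry file (duplicates, bad substituents, ...)."""


#: Canonical glycoside abbreviations (sugar names as used in registry files)
#: mapped from accepted spellings.
_GLYCOSIDE_ALIASES = {
    "glc": "glc",
    "glucoside": "glc",
    "gal": "gal",
    "galactoside": "gal",
    "ara": "ara",
    "arabinoside": "ara",
    "rut": "rut",
    "rutinoside": "rut",
    "sam": "sam",
    "sambubioside": "sam",
    "coumaroyl-sam": "coumaroyl-sam",
    "coumaroyl-sambubioside": "coumaroyl-sam",
}

GLYCOSIDES = frozenset(_GLYCOSIDE_ALIASES.values())

_CORE_CODES = ("H", "OH", "OCH3")


class StructuralForm(str, Enum):
    """The six pH-dependent forms of the anthocyanin chromophore."""

    FC = "FC"       # flavylium cation (low pH)
    QB4P = "QB4'"   # quinoidal base, deprotonated at 4'
    QB5 = "QB5"     # quinoidal base, deprotonated at 5
    QB7 = "QB7"     # quinoidal base, deprotonated at 7
    CP = "CP"       # carbinol pseudobase (hydrated)
    CH = "Ch"       # chalcone (ring-opened)

    @classmethod
    def parse(cls, code: str) -> "StructuralForm":
        code = code.strip()
        aliases = {"QB4p": cls.QB4P, "QB4'": cls.QB4P, "CH": cls.CH, "Ch": cls.CH}
        if code in aliases:
            return aliases[code]
        try:
            return cls(code)
        except ValueError:
            pass
        try:
            return cls[code]
        except KeyError:
            raise ValueError(
                f"unknown structural form {code!r}; expected one of "
                f"{[f.value for f in cls]}"
            ) from None


def normalize_substituent(code: str, slot: str) -> str:
    """Normalize a substituent code, raising :class:`SubstituentError`.

    Slots ``r1``/``r2`` accept H, OH, OCH3; slots ``r3``/``r4`` accept OH
    or a glycoside name (abbreviated or spelled out).
    """
    code = code.strip()
    if slot in ("r1", "r2"):
        if code in _CORE_CODES:
            return code
        raise SubstituentError(
            f"slot {slot}: unknown substituent {code!r} (expected H, OH or OCH3)"
        )
    if slot in ("r3", "r4"):
        if code == "OH":
            return code
        if code in _GLYCOSIDE_ALIASES:
            return _GLYCOSIDE_ALIASES[code]
        raise SubstituentError(
            f"slot {slot}: unknown substituent {code!r} "
            f"(expected OH or a glycoside name: {sorted(GLYCOSIDES)})"
        )
    raise ValueError(f"unknown substituent slot {slot!r}")


def is_glycoside(code: str) -> bool:
    return code in GLYCOSIDES or code in _GLYCOSIDE_ALIASES


def count_hydroxyls(r1: str, r2: str, r3: str, r4: str) -> int:
    """Count free hydroxyls on the flavonoid core (positions 3, 5, 7, 3', 4', 5').

    The 7- and 4'-hydroxyls are constitutive in this compound class and
    always contribute; 3 and 5 contribute unless glycosylated; 3' and 5'
    contribute when the substituent is OH.
    """
    r1 = normalize_substituent(r1, "r1")
    r2 = normalize_substituent(r2, "r2")
    r3 = normalize_substituent(r3, "r3")
    r4 = normalize_substituent(r4, "r4")
    return 2 + (r1 == "OH") + (r2 == "OH") + (r3 == "OH") + (r4 == "OH")


@dataclass(frozen=True)
class Compound:
    """One registry entry: substituent pattern, glycosylation and OH count.

    ``family`` is derived from the substituents ("anthocyanin" iff at
    least one of the 3-/5-positions is glycosylated) and ``n_oh`` from
    :func:`count_hydroxyls`; values passed explicitly are cross-checked.
    """

    name: str
    r1: str
    r2: str
    r3: str
    r4: str
    family: str = field(default="")
    n_oh: int = field(default=-1)

    def __post_init__(self):
        object.__setattr__(self, "r1", normalize_substituent(self.r1, "r1"))
        object.__setattr__(self, "r2", normalize_substituent(self.r2, "r2"))
        object.__setattr__(self, "r3", normalize_substituent(self.r3, "r3"))
        object.__setattr__(self, "r4", normalize_substituent(self.r4, "r4"))
        derived_family = (
            "anthocyanin" if (self.r3 != "OH" or self.r4 != "OH") else "anthocyanidin"
        )
        if self.family == "":
            object.__setattr__(self, "family", derived_family)
        elif self.family != derived_family:
            raise RegistryError(
                f"{self.name}: family {self.family!r} inconsistent with "
                f"substituents (expected {derived_family!r})"
            )
        derived_noh = count_hydroxyls(self.r1, self.r2, self.r3, self.r4)
        if self.n_oh == -1:
            object.__setattr__(self, "n_oh", derived_noh)
        elif self.n_oh != derived_noh:
            raise RegistryError(
                f"{self.name}: declared n_oh={self.n_oh} but substituent "
                f"pattern implies {derived_noh}"
            )


#: Map a ring position to the substituent occupying it.  Positions 7 and
#: 4' are constitutively hydroxylated for every compound in this class.
def _position_substituent(compound: Compound, position: str) -> str:
    table = {
        "3": compound.r3,
        "5": compound.r4,
        "7": "OH",
        "3'": compound.r1,
        "4'": "OH",
        "5'": compound.r2,
    }
    try:
        return table[position]
    except KeyError:
        raise ValueError(f"unknown ring position {position!r}") from None


#: Deprotonation site of each quinoidal base.
_QB_SITE = {
    StructuralForm.QB4P: "4'",
    StructuralForm.QB5: "5",
    StructuralForm.QB7: "7",
}

#: Canonical ordering of hydroxyl positions (used for reports and ties).
POSITION_ORDER = ("3", "5", "7", "3'", "4'", "5'")


def hydroxyl_positions(compound: Compound) -> tuple[str, ...]:
    """Ring positions carrying a free hydroxyl, in canonical order."""
    return tuple(
        p for p in POSITION_ORDER if _position_substituent(compound, p) == "OH"
    )


def available_forms(compound: Compound) -> frozenset[StructuralForm]:
    """Structural forms a compound can adopt.

    FC, CP and Ch always exist; each quinoidal base requires a free
    hydroxyl at its deprotonation site, so e.g. a 5-glycosylated
    anthocyanin cannot form QB5.
    """
    forms = {StructuralForm.FC, StructuralForm.CP, StructuralForm.CH}
    for qb, site in _QB_SITE.items():
        if _position_substituent(compound, site) == "OH":
            forms.add(qb)
    return frozenset(forms)


def load_registry(source: Union[str, Path, io.TextIOBase]) -> list[Compound]:
    """Load a compound registry from delimited text.

    The file must have header columns ``name, family, r1, r2, r3, r4``
    (comma- or tab-separated; an optional ``n_oh`` column is
    cross-checked against the substituent pattern).  Returns an empty
    list for an empty file.  Duplicate names or malformed substituents
    raise :class:`RegistryError` naming the offending row.
    """
    if isinstance(source, (str, Path)):
        with open(source, newline="") as fh:
            return load_registry(fh)
    text = source.read()
    if not text.strip():
        return []
    dialect = csv.Sniffer().sniff(text.splitlines()[0], delimiters=",\t")
    reader = csv.DictReader(io.StringIO(text), dialect=dialect)
    required = {"name", "family", "r1", "r2", "r3", "r4"}
    missing = required - set(reader.fieldnames or ())
    if missing:
        raise RegistryError(f"registry missing columns: {sorted(missing)}")
    compounds: list[Compound] = []
    seen: set[str] = set()
    for i, row in enumerate(reader, start=2):  # header is line 1
        name = (row["name"] or "").strip()
        if not name:
            raise RegistryError(f"row {i}: empty compound name")
        if name in seen:
            raise RegistryError(f"row {i}: duplicate compound name {name!r}")
        seen.add(name)
        try:
            compounds.append(
                Compound(
                    name=name,
                    family=(row["family"] or "").strip(),
                    r1=row["r1"],
                    r2=row["r2"],
                    r3=row["r3"],
                    r4=row["r4"],
                    n_oh=int(row["n_oh"]) if row.get("n_oh") else -1,
                )
            )
        except (SubstituentError, RegistryError, ValueError) as exc:
            raise RegistryError(f"row {i} ({name!r}): {exc}") from exc
    return compounds
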