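"""Conceptual-DFT reactivity descriptors and phenolic O-H bond energies.

All quantities derive from total molecular energies (heats of formation,
kcal/mol) of a species and its electron-abstracted / electron-added /
hydrogen-abstracted states, as produced by semi-empirical PM6 or PM7
geometry optimizations.  In the finite-difference approximation:

* ionization potential       I = E(N-1) - E(N)
* electron affinity          A = E(N) - E(N+1)
* chemical hardness          eta = (I - A) / 2
* chemical softness          S = 1 / (2 eta)
* electronegativity          chi = (I + A) / 2
* chemical potential         mu = -chi
* electrophilicity index     omega = mu^2 / (2 eta)
* O-H bond dissociation      BDE = E(A-O.) + E(H) - E(A-OH)

No unit conversion is performed: inputs and outputs are kcal/mol
(softness in (kcal/mol)^-1).  At eta = 0 softness and electrophilicity
are undefined and reported as explicit ``None`` values rather than
infinities, so downstream statistics cannot silently ingest them.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .chem_model import POSITION_ORDER, Compound, StructuralForm, hydroxyl_positions

__all__ = [
    "EnergyRecord",
    "BdeInput",
    "DescriptorSet",
    "NumericInputError",
    "MissingEnergyError",
    "StructuralError",
    "E_HYDROGEN_DEFAULT",
    "ionization_potential",
    "electron_affinity",
    "descriptor_set",
    "bde",
    "bde_min",
    "build_feature_table",
    "load_energy_table",
    "load_bde_table",
    "parse_mopac_heat",
]

#: Default heat of formation of atomic hydrogen (kcal/mol), the standard
#: semi-empirical value; overridable wherever a BDE is assembled.
E_HYDROGEN_DEFAULT = 52.1

METHODS = ("PM6", "PM7")


class NumericInputError(ValueError):
    """A non-finite energy was supplied."""


class MissingEnergyError(KeyError):
    """A required (compound, form) energy record is absent."""


class StructuralError(ValueError):
    """A BDE was requested at a position without a free hydroxyl."""


def _check_method(method: str) -> str:
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return method


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise NumericInputError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class EnergyRecord:
    """Energies (kcal/mol) of one structural form and its ionized states.

    ``e_cation`` is E(N-1), the electron-abstracted radical;
    ``e_anion`` is E(N+1), the electron-added radical.
    """

    compound_name: str
    form: StructuralForm
    method: str
    e_neutral: float
    e_cation: float
    e_anion: float

    def __post_init__(self):
        if not isinstance(self.form, StructuralForm):
            object.__setattr__(self, "form", StructuralForm.parse(str(self.form)))
        object.__setattr__(self, "method", _check_method(self.method))
        for f in ("e_neutral", "e_cation", "e_anion"):
            object.__setattr__(self, f, _check_finite(f, getattr(self, f)))


@dataclass(frozen=True)
class BdeInput:
    """Energies (kcal/mol) entering one O-H bond dissociation energy."""

    compound_name: str
    form: StructuralForm
    method: str
    position: str
    e_parent: float      # E(A-OH)
    e_phenoxyl: float    # E(A-O.)
    e_hydrogen: float = E_HYDROGEN_DEFAULT

    def __post_init__(self):
        if not isinstance(self.form, StructuralForm):
            object.__setattr__(self, "form", StructuralForm.parse(str(self.form)))
        object.__setattr__(self, "method", _check_method(self.method))
        if self.position not in POSITION_ORDER:
            raise ValueError(
                f"unknown OH position {self.position!r}; expected one of {POSITION_ORDER}"
            )
        for f in ("e_parent", "e_phenoxyl", "e_hydrogen"):
            object.__setattr__(self, f, _check_finite(f, getattr(self, f)))


@dataclass(frozen=True)
class DescriptorSet:
    """The seven conceptual-DFT descriptors of one structural form.

    ``softness`` and ``electrophilicity`` are ``None`` when hardness is
    zero (degenerate I = A).
    """

    i_pot: float
    e_aff: float
    hardness: float
    softness: Optional[float]
    electronegativity: float
    chem_potential: float
    electrophilicity: Optional[float]

    @property
    def undefined(self) -> tuple[str, ...]:
        """Names of descriptors undefined at zero hardness."""
        out = []
        if self.softness is None:
            out.append("softness")
        if self.electrophilicity is None:
            out.append("electrophilicity")
        return tuple(out)

    def value(self, short_name: str) -> float:
        """Look a descriptor up by its conventional symbol (I, A, eta, S, chi, mu, omega)."""
        attr = _SYMBOL_TO_ATTR[short_name]
        v = getattr(self, attr)
        if v is None:
            raise ValueError(
                f"descriptor {short_name} is undefined at zero hardness"
            )
        return v


_SYMBOL_TO_ATTR = {
    "I": "i_pot",
    "A": "e_aff",
    "eta": "hardness",
    "S": "softness",
    "chi": "electronegativity",
    "mu": "chem_potential",
    "omega": "electrophilicity",
}


def ionization_potential(rec: EnergyRecord) -> float:
    """I = E(N-1) - E(N), kcal/mol."""
    return rec.e_cation - rec.e_neutral


def electron_affinity(rec: EnergyRecord) -> float:
    """A = E(N) - E(N+1), kcal/mol."""
    return rec.e_neutral - rec.e_anion


def descriptor_set(rec: EnergyRecord) -> DescriptorSet:
    """All seven descriptors of one energy record."""
    i = ionization_potential(rec)
    a = electron_affinity(rec)
    eta = (i - a) / 2.0
    chi = (i + a) / 2.0
    mu = -chi
    if eta == 0.0:
        s = omega = None
    else:
        s = 1.0 / (2.0 * eta)
        omega = mu * mu / (2.0 * eta)
    return DescriptorSet(
        i_pot=i,
        e_aff=a,
        hardness=eta,
        softness=s,
        electronegativity=chi,
        chem_potential=mu,
        electrophilicity=omega,
    )


def bde(inp: BdeInput, compound: Optional[Compound] = None) -> float:
    """Homolytic O-H bond dissociation energy, BDE = E(A-O.) + E(H) - E(A-OH).

    When the parent :class:`~anthoqsar.chem_model.Compound` is supplied,
    the position is checked to carry a free hydroxyl.
    """
    if compound is not None and inp.position not in hydroxyl_positions(compound):
        raise StructuralError(
            f"{inp.compound_name}: position {inp.position} carries no free "
            f"hydroxyl (free OH at {hydroxyl_positions(compound)})"
        )
    return inp.e_phenoxyl + inp.e_hydrogen - inp.e_parent


def bde_min(bdes: Sequence[tuple[str, float]]) -> tuple[str, float]:
    """Lowest-energy entry of a (position, BDE) list.

    The minimum BDE marks the hydroxyl most prone to hydrogen-atom
    transfer.  Ties break by ring-position order 3 < 5 < 7 < 3' < 4' < 5'.
    """
    entries = list(bdes)
    if not entries:
        raise ValueError("bde_min of an empty list")
    order = {p: k for k, p in enumerate(POSITION_ORDER)}
    return min(entries, key=lambda pe: (pe[1], order.get(pe[0], len(order))))


# ---------------------------------------------------------------------------
# Feature-table assembly

#: Default QSAR feature columns: electron affinity and electronegativity of
#: the flavylium cation, ionization potential of the 7-quinoidal base, and
#: the core hydroxyl count.
DEFAULT_FEATURES = ("A_FC", "chi_FC", "I_QB7", "nOH")


def _parse_feature_name(name: str) -> tuple[str, Optional[StructuralForm]]:
    if name == "nOH":
        return "nOH", None
    sym, _, form = name.partition("_")
    if sym not in _SYMBOL_TO_ATTR or not form:
        raise ValueError(
            f"bad feature name {name!r}; expected '<symbol>_<form>' with symbol "
            f"in {sorted(_SYMBOL_TO_ATTR)} (e.g. 'chi_FC') or 'nOH'"
        )
    return sym, StructuralForm.parse(form)


def build_feature_table(
    registry: Sequence[Compound],
    energies: Iterable[EnergyRecord],
    method: str = "PM6",
    features: Sequence[str] = DEFAULT_FEATURES,
) -> pd.DataFrame:
    """Assemble the per-compound descriptor matrix used for QSAR modelling.

    Returns one row per registry compound (registry order preserved,
    index = compound name) with one column per requested feature.
    Feature names are ``<symbol>_<form>`` (``A_FC``, ``chi_FC``,
    ``I_QB7``, ...) or ``nOH``.  A missing (compound, form) energy
    record raises :class:`MissingEnergyError` naming both.
    """
    _check_method(method)
    by_key: dict[tuple[str, StructuralForm], EnergyRecord] = {}
    for rec in energies:
        if rec.method == method:
            by_key[(rec.compound_name, rec.form)] = rec
    parsed = [_parse_feature_name(f) for f in features]
    rows = []
    for comp in registry:
        row: dict[str, float] = {}
        cache: dict[StructuralForm, DescriptorSet] = {}
        for fname, (sym, form) in zip(features, parsed):
            if form is None:
                row[fname] = float(comp.n_oh)
                continue
            if form not in cache:
                try:
                    rec = by_key[(comp.name, form)]
                except KeyError:
                    raise MissingEnergyError(
                        f"no {method} energy record for compound {comp.name!r}, "
                        f"form {form.value}"
                    ) from None
                cache[form] = descriptor_set(rec)
            row[fname] = cache[form].value(sym)
        rows.append(row)
    return pd.DataFrame(rows, index=[c.name for c in registry], columns=list(features))


# ---------------------------------------------------------------------------
# File interfaces

def load_energy_table(path: Union[str, Path]) -> list[EnergyRecord]:
    """Read delimited text with columns compound, form, method, e_neutral,
    e_cation, e_anion into energy records."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"compound", "form", "method", "e_neutral", "e_cation", "e_anion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energy table missing columns: {sorted(missing)}")
    return [
        EnergyRecord(
            compound_name=str(r.compound),
            form=StructuralForm.parse(str(r.form)),
            method=str(r.method),
            e_neutral=r.e_neutral,
            e_cation=r.e_cation,
            e_anion=r.e_anion,
        )
        for r in df.itertuples()
    ]


def load_bde_table(path: Union[str, Path]) -> list[BdeInput]:
    """Read delimited text with columns compound, form, method, position,
    e_parent, e_phenoxyl, e_hydrogen into BDE inputs."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {
        "compound", "form", "method", "position",
        "e_parent", "e_phenoxyl", "e_hydrogen",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"BDE table missing columns: {sorted(missing)}")
    return [
        BdeInput(
            compound_name=str(r.compound),
            form=StructuralForm.parse(str(r.form)),
            method=str(r.method),
            position=str(r.position),
            e_parent=r.e_parent,
            e_phenoxyl=r.e_phenoxyl,
            e_hydrogen=r.e_hydrogen,
        )
        for r in df.itertuples()
    ]


_MOPAC_HEAT_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL", re.IGNORECASE
)


def parse_mopac_heat(text: str) -> float:
    """Extract the final heat of formation (kcal/mol) from MOPAC-style
    output text.

    Scans for the ``FINAL HEAT OF FORMATION = ... KCAL/MOL`` record and
    returns the last occurrence (the converged value in multi-step runs).
    """
    matches = _MOPAC_HEAT_RE.findall(text)
    if not matches:
        raise ValueError("no 'FINAL HEAT OF FORMATION' record found in output text")
    return float(matches[-1])
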