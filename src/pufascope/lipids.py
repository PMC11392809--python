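"""Shorthand diacyl glycerophospholipid nomenclature, classification and masses.

The quantification pipeline identifies every analyte by a shorthand name in
the dialect used throughout targeted lipidomics, e.g.::

    PE(18:0_20:4 + 3[O])     oxidized phosphatidylethanolamine, 3 extra oxygens
    PI(15:0/18:1-d7)         deuterated phosphatidylinositol internal standard
    PE(18:1Δ9/18:1Δ9)        double-bond positional isomer annotation

``HG(acyl SEP acyl)[ + n[O]]`` where the separator ``/`` asserts resolved
sn-1/sn-2 positions and ``_`` leaves them unresolved; an acyl token is
``carbons:double_bonds`` with optional ``Δpos`` (display-only double-bond
position) and ``-dk`` (k deuterium substitutions). Only diacyl PC, PE and PI
are modelled; ether/lyso species are rejected.

Masses are assembled from a frozen monoisotopic constants table: the
glycerophospho-headgroup backbone plus the two fatty acids minus two waters
(ester condensation), plus ``n`` oxygens for oxidized species, with deuterium
substitutions shifting each labelled hydrogen. Negative-mode adducts follow
the class rule used for MRM identification: PE and PI as [M-H]-, PC as
[M+OAc]-.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field

from ._masses import ACETIC_ACID, PROTON, formula_mass

__all__ = [
    "Adduct",
    "FattyAcyl",
    "LipidParseError",
    "PhospholipidSpecies",
    "UnsaturationClass",
    "UnsupportedStructureError",
    "classify_acyl",
    "class_adduct",
    "fragment_mz",
    "molecular_mass",
    "parse_species",
]

HEADGROUPS = ("PC", "PE", "PI")

#: Glycerophospho-headgroup backbone formulas (glycerol + phosphate + headgroup
#: alcohol, fully condensed): glycerophosphocholine, -ethanolamine, -inositol.
_BACKBONES: dict[str, dict[str, int]] = {
    "PC": {"C": 8, "H": 20, "N": 1, "O": 6, "P": 1},
    "PE": {"C": 5, "H": 14, "N": 1, "O": 6, "P": 1},
    "PI": {"C": 9, "H": 19, "O": 11, "P": 1},
}


class LipidParseError(ValueError):
    """A species name does not conform to the shorthand grammar."""


class UnsupportedStructureError(ValueError):
    """Structurally valid shorthand outside the modelled chemistry (non-diacyl etc.)."""


class UnsaturationClass(str, enum.Enum):
    SFA = "SFA"
    MUFA = "MUFA"
    PUFA = "PUFA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Adduct(str, enum.Enum):
    """Negative-mode adducts used for precursor (Q1) selection."""

    M_MINUS_H = "[M-H]-"
    M_PLUS_OAC = "[M+OAc]-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Class rule: oxidized PE/PI are identified from [M-H]-, oxidized PC from [M+OAc]-.
CLASS_ADDUCT: dict[str, Adduct] = {
    "PC": Adduct.M_PLUS_OAC,
    "PE": Adduct.M_MINUS_H,
    "PI": Adduct.M_MINUS_H,
}


def class_adduct(headgroup: str) -> Adduct:
    """Negative-mode adduct used for a phospholipid class."""
    try:
        return CLASS_ADDUCT[headgroup]
    except KeyError:
        raise UnsupportedStructureError(f"unsupported headgroup: {headgroup!r}") from None


_ACYL_RE = re.compile(r"^(?P<c>\d+):(?P<db>\d+)(?:Δ(?P<pos>\d+))?(?:-d(?P<d>\d+))?$")
# the oxygen annotation is printed inside the parentheses ("PE(18:0_20:4 + 3[O])");
# it is also accepted after them
_NAME_RE = re.compile(
    r"^(?P<hg>[A-Za-z][A-Za-z0-9]*)"
    r"\((?P<chains>[^)]*?)(?:\s*\+\s*(?P<ox_in>\d+)\[O\]\s*)?\)"
    r"(?:\s*\+\s*(?P<ox_out>\d+)\[O\])?$"
)


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """One fatty acyl chain: ``carbons:double_bonds`` with optional labels.

    ``db_position_note`` (the Δn annotation) is display metadata: it
    distinguishes positional isomers for reporting but never affects mass or
    unsaturation class (positional isomers are isobaric).
    """

    carbons: int
    double_bonds: int
    deuterium_count: int = 0
    db_position_note: str | None = field(default=None)

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"acyl needs >=2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the maximum "
                f"{self.carbons // 2} double bonds for {self.carbons} carbons"
            )
        if self.deuterium_count < 0:
            raise ValueError("deuterium_count must be >= 0")

    @property
    def unsaturation_class(self) -> UnsaturationClass:
        return classify_acyl(self)

    def formula(self) -> Counter:
        """Element counts of the free fatty acid CnH(2n-2db)O2, with D substitutions."""
        n_h = 2 * self.carbons - 2 * self.double_bonds
        if self.deuterium_count > n_h:
            raise ValueError("more deuterium labels than hydrogens on the chain")
        counts = Counter(
            {"C": self.carbons, "H": n_h - self.deuterium_count, "O": 2}
        )
        if self.deuterium_count:
            counts["D"] = self.deuterium_count
        return counts

    def __str__(self) -> str:
        s = f"{self.carbons}:{self.double_bonds}"
        if self.db_position_note:
            s += f"Δ{self.db_position_note}"
        if self.deuterium_count:
            s += f"-d{self.deuterium_count}"
        return s


@dataclass(frozen=True)
class PhospholipidSpecies:
    """A diacyl glycerophospholipid, optionally oxidized and/or deuterated."""

    headgroup: str
    acyls: tuple[FattyAcyl, FattyAcyl]
    sn_resolved: bool = False
    oxygens: int = 0

    def __post_init__(self) -> None:
        if self.headgroup not in HEADGROUPS:
            raise UnsupportedStructureError(
                f"unsupported headgroup: {self.headgroup!r} (diacyl PC/PE/PI only)"
            )
        if len(self.acyls) != 2:
            raise UnsupportedStructureError("only diacyl species are modelled")
        if self.oxygens < 0:
            raise ValueError("oxygens must be >= 0")

    @property
    def canonical_name(self) -> str:
        sep = "/" if self.sn_resolved else "_"
        chains = f"{self.acyls[0]}{sep}{self.acyls[1]}"
        if self.oxygens:
            chains += f" + {self.oxygens}[O]"
        return f"{self.headgroup}({chains})"

    @property
    def is_deuterated(self) -> bool:
        return any(a.deuterium_count for a in self.acyls)

    @property
    def contains_pufa(self) -> bool:
        return any(a.double_bonds >= 2 for a in self.acyls)

    def formula(self) -> Counter:
        counts = Counter(_BACKBONES[self.headgroup])
        for acyl in self.acyls:
            counts.update(acyl.formula())
        # two ester condensations remove one water each
        counts["H"] -= 4
        counts["O"] -= 2
        counts["O"] += self.oxygens
        return counts

    def with_oxygens(self, oxygens: int) -> "PhospholipidSpecies":
        return PhospholipidSpecies(self.headgroup, self.acyls, self.sn_resolved, oxygens)

    def __str__(self) -> str:
        return self.canonical_name


def _parse_acyl(token: str, name: str) -> FattyAcyl:
    m = _ACYL_RE.match(token)
    if m is None:
        raise LipidParseError(f"malformed acyl token {token!r} in {name!r}")
    try:
        return FattyAcyl(
            carbons=int(m["c"]),
            double_bonds=int(m["db"]),
            deuterium_count=int(m["d"] or 0),
            db_position_note=m["pos"],
        )
    except ValueError as exc:
        raise LipidParseError(f"invalid acyl {token!r} in {name!r}: {exc}") from None


def parse_species(name: str) -> PhospholipidSpecies:
    """Parse a shorthand species name; inverse of ``PhospholipidSpecies.canonical_name``.

    Raises :class:`LipidParseError` for names outside the grammar and
    :class:`UnsupportedStructureError` for ether/lyso/poly-acyl structures.
    """
    m = _NAME_RE.match(name.strip())
    if m is None:
        raise LipidParseError(f"malformed species name: {name!r}")
    hg = m["hg"]
    if hg not in HEADGROUPS:
        raise UnsupportedStructureError(
            f"unsupported headgroup {hg!r} in {name!r} (diacyl PC/PE/PI only)"
        )
    if m["ox_in"] and m["ox_out"]:
        raise LipidParseError(f"duplicate oxygen annotation in {name!r}")
    oxygens = int(m["ox_in"] or m["ox_out"] or 0)
    chains = m["chains"]
    if chains.startswith(("O-", "P-")) or "O-" in chains or "P-" in chains:
        raise UnsupportedStructureError(f"ether-linked species not modelled: {name!r}")
    tokens = re.split(r"([/_])", chains)
    acyl_tokens = tokens[0::2]
    seps = tokens[1::2]
    if len(acyl_tokens) > 2:
        raise UnsupportedStructureError(
            f"{name!r} has {len(acyl_tokens)} acyl chains; only diacyl species are modelled"
        )
    if len(acyl_tokens) != 2 or not all(acyl_tokens):
        raise UnsupportedStructureError(
            f"{name!r} is not diacyl; lyso/mono-acyl species are not modelled"
        )
    acyls = tuple(_parse_acyl(tok, name) for tok in acyl_tokens)
    return PhospholipidSpecies(
        headgroup=hg,
        acyls=acyls,  # type: ignore[arg-type]
        sn_resolved=(seps[0] == "/"),
        oxygens=oxygens,
    )


def classify_acyl(acyl: FattyAcyl) -> UnsaturationClass:
    """SFA (0 double bonds), MUFA (1) or PUFA (>=2); labels do not affect class."""
    if acyl.double_bonds == 0:
        return UnsaturationClass.SFA
    if acyl.double_bonds == 1:
        return UnsaturationClass.MUFA
    return UnsaturationClass.PUFA


def molecular_mass(
    species: PhospholipidSpecies | str, adduct: Adduct | None = None
) -> float:
    """Monoisotopic m/z of a species under a negative-mode adduct.

    With ``adduct=None`` the class rule is applied ([M+OAc]- for PC, [M-H]-
    for PE/PI). The neutral monoisotopic mass is shifted by -proton for
    [M-H]- and +acetate (acetic acid - proton) for [M+OAc]-.
    """
    if isinstance(species, str):
        species = parse_species(species)
    if adduct is None:
        adduct = class_adduct(species.headgroup)
    neutral = formula_mass(species.formula())
    if adduct is Adduct.M_MINUS_H:
        return neutral - PROTON
    return neutral + ACETIC_ACID - PROTON


def fragment_mz(acyl: FattyAcyl, oxygens: int = 0) -> float:
    """m/z of the (oxidized) fatty acid carboxylate anion [FA + n·O - H]-."""
    if oxygens < 0:
        raise ValueError("oxygens must be >= 0")
    counts = acyl.formula()
    counts["O"] += oxygens
    return formula_mass(counts) - PROTON
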