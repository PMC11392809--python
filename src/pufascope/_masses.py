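"""Frozen monoisotopic mass constants.

Values are CODATA/AME-derived monoisotopic atomic masses in unified atomic
mass units (Da). They are shipped as a versioned constants table rather than
computed at run time so that reported m/z values are stable across
environments and dependency upgrades.
"""

from __future__ import annotations

from types import MappingProxyType

#: Monoisotopic masses of the elements (and the deuterium isotope) that occur
#: in diacyl glycerophospholipids. ``D`` denotes deuterium (2H).
MONOISOTOPIC: MappingProxyType[str, float] = MappingProxyType(
    {
        "H": 1.00782503207,
        "D": 2.01410177812,
        "C": 12.0,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "P": 30.97376163,
    }
)

#: Mass of a proton; [M-H]- m/z = M - PROTON (electron mass accounted for).
PROTON: float = 1.007276466621

#: Neutral acetic acid (C2H4O2); the acetate adduct shift is ACETIC_ACID - PROTON.
ACETIC_ACID: float = 2 * MONOISOTOPIC["C"] + 4 * MONOISOTOPIC["H"] + 2 * MONOISOTOPIC["O"]

#: Water, used for the two ester condensations on the glycerol backbone.
WATER: float = 2 * MONOISOTOPIC["H"] + MONOISOTOPIC["O"]

#: Mass difference introduced by replacing 1H with 2H.
DEUTERIUM_SHIFT: float = MONOISOTOPIC["D"] - MONOISOTOPIC["H"]


def formula_mass(formula: dict[str, int]) -> float:
    """Monoisotopic mass of an element-count formula, e.g. ``{"C": 2, "H": 4, "O": 2}``."""
    try:
        return sum(MONOISOTOPIC[el] * n for el, n in formula.items())
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown element in formula: {exc.args[0]!r}") from None
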