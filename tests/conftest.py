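"""Shared fixtures and independent oracles for the test suite.

Oracles here are deliberately coded along different routes than the package:
the mass oracle assembles molecules from neutral building blocks and sums
atomic masses with pyteomics; the fatty-acyl oracle is an explicit
(species x sn-slot) double loop; the FDR oracle restates the two-stage
definition with scalar loops.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pufascope.lipids import parse_species

# species names as printed in targeted phospholipidomics read-outs, incl.
# oxidized, deuterated and positional-isomer-annotated forms
SPECIES_CORPUS = [
    "PE(18:0_20:4)",
    "PE(18:0_22:4)",
    "PE(18:0_20:4 + 3[O])",
    "PE(16:0/20:4)",
    "PE(16:0/20:4 + 1[O])",
    "PE(16:0/20:4 + 2[O])",
    "PE(14:0/14:0)",
    "PE(15:0/18:1-d7)",
    "PE(18:1Δ9/18:1Δ9)",
    "PE(18:1Δ6/18:1Δ9)",
    "PC(16:0/20:4)",
    "PC(16:0/20:4 + 1[O])",
    "PC(16:0/20:4 + 2[O])",
    "PC(16:0/20:4 + 3[O])",
    "PC(14:0/14:0)",
    "PC(15:0/18:1-d7)",
    "PI(18:1/18:1)",
    "PI(15:0/18:1-d7)",
    "PI(18:0_20:4)",
    "PI(16:0/18:1)",
    "PE(16:0/16:0)",
    "PE(18:1/18:1)",
    "PC(16:0/16:1)",
    "PI(18:0/18:2)",
]


@pytest.fixture(scope="session")
def species_corpus() -> list[str]:
    return list(SPECIES_CORPUS)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

_HEAD_ALCOHOL = {"PC": "C5H13NO", "PE": "C2H7NO", "PI": "C6H12O6"}


def oracle_formula(name: str) -> str:
    """Element formula via neutral building blocks: glycerol + phosphoric acid
    + headgroup alcohol + both fatty acids - 4 waters (2 phosphoester + 2
    ester condensations). Independent of the package's backbone tables."""
    sp = parse_species(name)
    from collections import Counter
    import re

    def add(counter: Counter, formula: str, sign: int = 1) -> None:
        for el, n in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
            if el:
                counter[el] += sign * (int(n) if n else 1)

    counts: Counter = Counter()
    add(counts, "C3H8O3")  # glycerol
    add(counts, "H3PO4")  # phosphoric acid
    add(counts, _HEAD_ALCOHOL[sp.headgroup])
    total_d = 0
    for acyl in sp.acyls:
        h = 2 * acyl.carbons - 2 * acyl.double_bonds
        add(counts, f"C{acyl.carbons}H{h}O2")
        total_d += acyl.deuterium_count
    add(counts, "H8O4", sign=-1)  # four condensations
    counts["H"] -= total_d
    counts["O"] += sp.oxygens
    parts = []
    for el in ("C", "H", "N", "O", "P"):
        if counts.get(el):
            parts.append(f"{el}{counts[el]}")
    if total_d:
        parts.append(f"H[2]{total_d}")
    return "".join(parts)


def oracle_mz(name: str, adduct: str) -> float:
    """Atomic-mass-sum m/z oracle via pyteomics + CODATA proton mass."""
    from pyteomics.mass import calculate_mass
    from scipy.constants import physical_constants

    proton = physical_constants["proton mass in u"][0]
    neutral = calculate_mass(formula=oracle_formula(name))
    if adduct == "[M-H]-":
        return neutral - proton
    if adduct == "[M+OAc]-":
        return neutral + calculate_mass(formula="C2H4O2") - proton
    raise ValueError(adduct)


def oracle_fa_distribution(rel: pd.DataFrame) -> tuple[dict, dict]:
    """Explicit (species x sn-slot) double loop over half-intensities."""
    shares: dict[str, float] = {}
    fractions = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0}
    for _, row in rel.iterrows():
        sp = parse_species(row["species"])
        for slot in (0, 1):
            acyl = sp.acyls[slot]
            half = row["rel_pct"] / 2.0
            shares[str(acyl)] = shares.get(str(acyl), 0.0) + half
            if acyl.double_bonds == 0:
                fractions["SFA"] += half
            elif acyl.double_bonds == 1:
                fractions["MUFA"] += half
            else:
                fractions["PUFA"] += half
    return shares, fractions


def oracle_two_stage_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Scalar restatement of the two-stage step-up definition.

    Stage 1: step-up at q/(1+q) estimates m0 = m - r1; stage 2: step-up at
    q*m/m0 gives the rejections; m0 = 0 rejects everything.
    """

    def step_up(sorted_p, level, m):
        r = 0
        for j, pj in enumerate(sorted_p, start=1):
            if pj <= level * j / m:
                r = j
        return r

    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: (p[i], i))
    sorted_p = [p[i] for i in order]
    r1 = step_up(sorted_p, q / (1.0 + q), m)
    m0 = m - r1
    rejected = np.zeros(m, dtype=bool)
    if m0 == 0:
        rejected[:] = True
        return rejected
    r2 = step_up(sorted_p, q * m / m0, m)
    for i in order[:r2]:
        rejected[i] = True
    return rejected


def random_signal_table(
    rng: np.random.Generator, n_species: int = 8, sample_id: str = "S1"
) -> pd.DataFrame:
    """A random single-sample, single-class signal table for property tests."""
    pool = [
        "PE(16:0/16:0)", "PE(16:0/18:1)", "PE(18:1/18:1)", "PE(18:0_20:4)",
        "PE(18:0_22:4)", "PE(16:0/20:4)", "PE(18:0/18:2)", "PE(14:0/16:1)",
        "PE(18:0/18:0)", "PE(16:1/18:1)",
    ]
    chosen = rng.choice(pool, size=min(n_species, len(pool)), replace=False)
    rows = []
    for name in chosen:
        intensity = rng.uniform(10.0, 1e4)
        split = rng.uniform(0.0, 0.4)
        rows.append((sample_id, name, "fa1", intensity * (1 + split), 5.0))
        rows.append((sample_id, name, "fa2", intensity * (1 - split), 5.0))
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "fragment_id", "intensity", "rt_min"]
    )
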