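"""MRM signal tables -> quantitative phospholipidome read-outs.

Implements the normalization and composition arithmetic of a targeted
(MRM-based) phospholipidomics workflow:

* per-species signal = mean of the (up to two) fatty acid anion fragments;
* absolute amounts = signal / class-specific deuterated internal standard
  signal x spiked amount (nmol) / protein mass (mg);
* relative intensities = per-class percentages summing to 100;
* fatty-acyl decomposition: each diacyl species contributes half its relative
  intensity to each of its two acyls, aggregated into SFA/MUFA/PUFA fractions
  and the PUFA:MUFA ratio;
* category split: PUFA-containing vs exclusively SFA/MUFA species;
* treatment-vs-vehicle percent changes and fold changes.

All tables are tidy :class:`pandas.DataFrame` objects; species are shorthand
names (see :mod:`pufascope.lipids`). Internal standards are auto-detected via
their deuterium label and excluded from every composition metric; species
listed in an explicit standards table are excluded as well (covers the
non-deuterated DMPC/DMPE-style standards).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .lipids import PhospholipidSpecies, UnsaturationClass, parse_species

log = logging.getLogger(__name__)

__all__ = [
    "CompositionResult",
    "MissingSignalError",
    "absolute_amounts",
    "category_proportions",
    "compute_composition",
    "fa_distribution",
    "fold_changes",
    "group_mean_fractions",
    "percent_change_vs_vehicle",
    "pufa_mufa_ratio",
    "relative_intensities",
    "species_signal",
    "species_signals",
]

SIGNAL_COLUMNS = ("sample_id", "species", "fragment_id", "intensity")


class MissingSignalError(KeyError):
    """No fragment signal available for a requested (sample, species)."""


@lru_cache(maxsize=4096)
def _parsed(name: str) -> PhospholipidSpecies:
    return parse_species(name)


def _validate_signals(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SIGNAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"signal table is missing columns: {missing}")
    if table["intensity"].lt(0).any() or ~np.isfinite(table["intensity"]).all():
        raise ValueError("intensities must be finite and non-negative")
    dup = table.duplicated(subset=["sample_id", "species", "fragment_id"])
    if dup.any():
        row = table.index[dup][0]
        raise ValueError(
            f"duplicate (sample, species, fragment) record at row {row}: "
            f"{table.loc[row, ['sample_id', 'species', 'fragment_id']].tolist()}"
        )
    return table


def species_signals(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse fragments: mean fragment intensity per (sample, species).

    Implements the dual-fragment rule of diacyl MRM quantification — when both
    fatty acid anion transitions were recorded, their mean is the species
    signal; a single recorded fragment stands alone.
    """
    table = _validate_signals(table)
    out = (
        table.groupby(["sample_id", "species"], sort=True)["intensity"]
        .mean()
        .reset_index(name="signal")
    )
    return out


def species_signal(table: pd.DataFrame, sample_id: str, species: str) -> float:
    """Scalar species signal for one sample; raises :class:`MissingSignalError`."""
    sub = table[(table["sample_id"] == sample_id) & (table["species"] == species)]
    if sub.empty:
        raise MissingSignalError(f"no fragment signal for {species!r} in {sample_id!r}")
    return float(sub["intensity"].mean())


def _standard_names(standards: pd.DataFrame | None) -> set[str]:
    if standards is None:
        return set()
    return set(standards["species"].astype(str))


def _is_internal_standard(name: str, explicit: set[str]) -> bool:
    if name in explicit:
        return True
    try:
        return _parsed(name).is_deuterated
    except ValueError:
        return False


def absolute_amounts(
    table: pd.DataFrame,
    annotations: pd.DataFrame,
    standards: pd.DataFrame,
) -> pd.DataFrame:
    """Absolute amounts in nmol per mg protein.

    amount = (species signal / class IS signal) x IS amount (nmol) / protein (mg)

    The internal standard for a class is its deuterated standard listed in
    ``standards`` (columns ``species``, ``amount_nmol``); standards themselves
    are excluded from the output. The returned frame carries an ``extension``
    flag: absolute quantification is the established read-out for PE and PI,
    PC values are reported as an extension.
    """
    signals = species_signals(table)
    std_names = _standard_names(standards)
    std_by_class: dict[str, tuple[str, float]] = {}
    for _, row in standards.iterrows():
        sp = _parsed(str(row["species"]))
        amount = float(row["amount_nmol"])
        if amount <= 0:
            raise ValueError(f"internal standard amount must be > 0 for {row['species']}")
        if sp.is_deuterated:
            std_by_class[sp.headgroup] = (str(row["species"]), amount)

    ann = annotations.set_index("sample_id")
    records: list[dict] = []
    for sample_id, sub in signals.groupby("sample_id"):
        if sample_id not in ann.index:
            raise ValueError(f"sample {sample_id!r} missing from annotations")
        protein = ann.loc[sample_id].get("protein_mg", np.nan)
        if pd.isna(protein) or protein <= 0:
            raise ValueError(f"protein mass missing or non-positive for sample {sample_id!r}")
        by_species = dict(zip(sub["species"], sub["signal"]))
        for name, sig in by_species.items():
            if _is_internal_standard(name, std_names):
                continue
            hg = _parsed(name).headgroup
            if hg not in std_by_class:
                raise ValueError(f"no deuterated internal standard supplied for class {hg}")
            is_name, is_amount = std_by_class[hg]
            if is_name not in by_species:
                raise ValueError(
                    f"internal standard {is_name!r} not measured in sample {sample_id!r}"
                )
            is_signal = by_species[is_name]
            if is_signal <= 0:
                raise ValueError(
                    f"internal standard signal is zero for {is_name!r} in {sample_id!r}"
                )
            records.append(
                {
                    "sample_id": sample_id,
                    "species": name,
                    "headgroup": hg,
                    "amount_nmol_per_mg": sig / is_signal * is_amount / float(protein),
                    "extension": hg == "PC",
                }
            )
    return pd.DataFrame.from_records(
        records, columns=["sample_id", "species", "headgroup", "amount_nmol_per_mg", "extension"]
    ).sort_values(["sample_id", "headgroup", "species"], ignore_index=True)


def relative_intensities(
    table: pd.DataFrame,
    standards: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-class relative intensities: each species as % of its class sum (=100).

    Internal standards (deuterated or explicitly listed) are excluded before
    normalization. Classes with zero total signal yield missing values with a
    logged warning.
    """
    signals = species_signals(table)
    std_names = _standard_names(standards)
    keep = ~signals["species"].map(lambda s: _is_internal_standard(s, std_names))
    signals = signals[keep].copy()
    signals["headgroup"] = signals["species"].map(lambda s: _parsed(s).headgroup)
    out = []
    for (sample_id, hg), sub in signals.groupby(["sample_id", "headgroup"]):
        total = sub["signal"].sum()
        if total <= 0:
            log.warning("class %s in sample %s has zero total signal", hg, sample_id)
            rel = np.full(len(sub), np.nan)
        else:
            rel = 100.0 * sub["signal"].to_numpy() / total
        out.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "headgroup": hg,
                    "species": sub["species"].to_numpy(),
                    "rel_pct": rel,
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["sample_id", "headgroup", "species", "rel_pct"])
    return pd.concat(out, ignore_index=True).sort_values(
        ["sample_id", "headgroup", "species"], ignore_index=True
    )


def _acyl_key(acyl) -> str:
    return str(acyl)


def fa_distribution(rel: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """Fatty-acyl shares and SFA/MUFA/PUFA fractions for one (sample, class) panel.

    Each diacyl species contributes half of its relative intensity to each of
    its two acyls regardless of sn assignment; shares are aggregated by acyl
    identity (carbons:double_bonds plus any Δ/deuterium annotation) and summed
    per unsaturation class.

    Parameters
    ----------
    rel : DataFrame with columns ``species`` and ``rel_pct`` for one panel.
    """
    shares: dict[str, float] = {}
    classes = {c.value: 0.0 for c in UnsaturationClass}
    for name, pct in zip(rel["species"], rel["rel_pct"]):
        sp = _parsed(name)
        for acyl in sp.acyls:
            half = float(pct) / 2.0
            key = _acyl_key(acyl)
            shares[key] = shares.get(key, 0.0) + half
            classes[acyl.unsaturation_class.value] += half
    series = pd.Series(shares, dtype=float).sort_index()
    series.index.name = "acyl"
    return series, classes


def pufa_mufa_ratio(fractions: dict[str, float]) -> float:
    """PUFA% / MUFA%; NaN (with warning) when there is no MUFA but some PUFA."""
    mufa = fractions["MUFA"]
    pufa = fractions["PUFA"]
    if mufa == 0:
        if pufa == 0:
            return 0.0
        warnings.warn("MUFA fraction is zero; PUFA:MUFA ratio undefined", stacklevel=2)
        return float("nan")
    return pufa / mufa


def category_proportions(rel: pd.DataFrame) -> dict[str, float]:
    """% of class intensity in PUFA-containing vs exclusively-SFA/MUFA species."""
    pufa_containing = 0.0
    sfa_mufa_only = 0.0
    for name, pct in zip(rel["species"], rel["rel_pct"]):
        if _parsed(name).contains_pufa:
            pufa_containing += float(pct)
        else:
            sfa_mufa_only += float(pct)
    return {"pufa_containing": pufa_containing, "sfa_mufa_only": sfa_mufa_only}


@dataclass
class CompositionResult:
    """Tidy per-(sample, class) composition tables."""

    relative: pd.DataFrame
    acyl_shares: pd.DataFrame
    fractions: pd.DataFrame
    categories: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def compute_composition(
    table: pd.DataFrame,
    standards: pd.DataFrame | None = None,
) -> CompositionResult:
    """Full composition read-out for every sample and class in a signal table."""
    rel = relative_intensities(table, standards)
    acyl_rows, frac_rows, cat_rows = [], [], []
    for (sample_id, hg), sub in rel.groupby(["sample_id", "headgroup"]):
        shares, fracs = fa_distribution(sub)
        for acyl, share in shares.items():
            acyl_rows.append(
                {"sample_id": sample_id, "headgroup": hg, "acyl": acyl, "share_pct": share}
            )
        frac_rows.append(
            {
                "sample_id": sample_id,
                "headgroup": hg,
                "sfa_pct": fracs["SFA"],
                "mufa_pct": fracs["MUFA"],
                "pufa_pct": fracs["PUFA"],
                "pufa_mufa_ratio": pufa_mufa_ratio(fracs),
            }
        )
        cats = category_proportions(sub)
        cat_rows.append(
            {
                "sample_id": sample_id,
                "headgroup": hg,
                "pufa_containing_pct": cats["pufa_containing"],
                "sfa_mufa_only_pct": cats["sfa_mufa_only"],
            }
        )
    return CompositionResult(
        relative=rel,
        acyl_shares=pd.DataFrame(
            acyl_rows, columns=["sample_id", "headgroup", "acyl", "share_pct"]
        ),
        fractions=pd.DataFrame(
            frac_rows,
            columns=[
                "sample_id",
                "headgroup",
                "sfa_pct",
                "mufa_pct",
                "pufa_pct",
                "pufa_mufa_ratio",
            ],
        ),
        categories=pd.DataFrame(
            cat_rows,
            columns=["sample_id", "headgroup", "pufa_containing_pct", "sfa_mufa_only_pct"],
        ),
    )


def group_mean_fractions(
    fractions: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Group-level composition summary: mean class fractions and their ratio.

    Replicate fractions are averaged per (group, headgroup) and the group
    PUFA:MUFA ratio is the ratio of those mean fractions — the convention
    behind mean-composition summaries (pie/radar charts), which is less noisy
    than averaging per-replicate ratios.
    """
    merged = fractions.merge(annotations[["sample_id", "group"]], on="sample_id")
    out = (
        merged.groupby(["group", "headgroup"], sort=True)[
            ["sfa_pct", "mufa_pct", "pufa_pct"]
        ]
        .mean()
        .reset_index()
    )
    out["pufa_mufa_ratio"] = out["pufa_pct"] / out["mufa_pct"]
    return out


def _group_samples(
    annotations: pd.DataFrame, group: str, timepoint: float | None
) -> list[str]:
    sel = annotations["group"] == group
    if timepoint is not None and "timepoint_h" in annotations.columns:
        sel &= annotations["timepoint_h"] == timepoint
    return annotations.loc[sel, "sample_id"].tolist()


def _group_means(
    amounts: pd.DataFrame, samples: list[str], value_col: str
) -> pd.Series:
    sub = amounts[amounts["sample_id"].isin(samples)]
    return sub.groupby("species")[value_col].mean()


def percent_change_vs_vehicle(
    amounts: pd.DataFrame,
    annotations: pd.DataFrame,
    treatment: str,
    vehicle: str = "Veh",
    timepoint: float | None = None,
    value_col: str = "amount_nmol_per_mg",
) -> pd.DataFrame:
    """Mean percent change against vehicle per species: 100·(T̄ − V̄)/V̄."""
    t_samples = _group_samples(annotations, treatment, timepoint)
    v_samples = _group_samples(annotations, vehicle, timepoint)
    if not t_samples or not v_samples:
        raise ValueError(
            f"need >=1 replicate in both groups ({treatment!r}: {len(t_samples)}, "
            f"{vehicle!r}: {len(v_samples)})"
        )
    t_mean = _group_means(amounts, t_samples, value_col)
    v_mean = _group_means(amounts, v_samples, value_col)
    species = sorted(set(t_mean.index) & set(v_mean.index))
    rows = []
    for sp in species:
        v = v_mean[sp]
        if v == 0:
            log.warning("vehicle mean is zero for %s; percent change undefined", sp)
            pct = np.nan
        else:
            pct = 100.0 * (t_mean[sp] - v) / v
        rows.append({"species": sp, "pct_change": pct})
    return pd.DataFrame(rows, columns=["species", "pct_change"])


def fold_changes(
    amounts: pd.DataFrame,
    annotations: pd.DataFrame,
    contrast: tuple[str, str],
    timepoint: float | None = None,
    value_col: str = "amount_nmol_per_mg",
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Per-species fold change (treated/vehicle group means) and log2 fold change.

    ``epsilon`` is the floor added to zero means before taking log2; by
    default it is the smallest positive observed value x 1e-3. Species whose
    means are both zero are reported as missing.
    """
    treated, vehicle = contrast
    t_mean = _group_means(amounts, _group_samples(annotations, treated, timepoint), value_col)
    v_mean = _group_means(amounts, _group_samples(annotations, vehicle, timepoint), value_col)
    if t_mean.empty or v_mean.empty:
        raise ValueError(f"both groups of contrast {contrast} must be non-empty")
    if epsilon is None:
        positive = amounts.loc[amounts[value_col] > 0, value_col]
        epsilon = float(positive.min()) * 1e-3 if not positive.empty else 1e-12
    rows = []
    for sp in sorted(set(t_mean.index) & set(v_mean.index)):
        t, v = float(t_mean[sp]), float(v_mean[sp])
        if t == 0 and v == 0:
            fc = np.nan
            l2 = np.nan
        else:
            fc = t / v if v > 0 else np.inf
            tf = t if t > 0 else epsilon
            vf = v if v > 0 else epsilon
            if t == 0 or v == 0:
                log.warning("zero group mean for %s; log2 FC floored at epsilon=%g", sp, epsilon)
            l2 = float(np.log2(tf / vf))
        rows.append({"species": sp, "fold_change": fc, "log2fc": l2})
    return pd.DataFrame(rows, columns=["species", "fold_change", "log2fc"])
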