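"""Oxidized phospholipid identification and quantification.

Oxidized PC/PE/PI species carrying 1–3 extra oxygens are identified by their
MRM transitions (class-specific precursor adduct -> oxidized fatty acid anion)
and by eluting inside a predicted retention-time window. Windows are predicted
with an effective-carbon-number (ECN) model: within a (headgroup, n[O])
stratum the window centre is linear in ECN = total acyl carbons - 2 x total
double bonds, the standard reversed-phase retention predictor. Reference
species with measured windows anchor the model; strata observed at a single
ECN value borrow the slope from the same class's non-oxidized (0[O])
calibration or, failing that, use a configurable default.

Oxygen-level effects are deliberately modelled as stratum-specific intercepts
and half-widths rather than a single per-oxygen shift: measured reference
windows are non-monotone in n[O] (the 2[O] species of a backbone elutes
slightly later than its 1[O] species while 3[O] elutes much earlier), which a
single additive oxygen term cannot represent.

Surviving signals per (sample, species, n[O]) are summed over isomers without
discrimination and normalized to the class standard (DMPE for PE; DMPC for PC
and PI) and the cell number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import (
    PhospholipidSpecies,
    class_adduct,
    fragment_mz,
    molecular_mass,
    parse_species,
)

log = logging.getLogger(__name__)

__all__ = [
    "ECNCalibration",
    "ReferenceWindow",
    "aggregate_oxidation",
    "build_ox_transitions",
    "ecn",
    "filter_signals_by_rt",
    "fit_ecn_calibration",
    "predict_rt_window",
]

#: Normalization standards for oxidized-species quantification: oxidized PE is
#: normalized to DMPE, oxidized PC and PI to DMPC.
OX_NORMALIZATION_STANDARD = {
    "PE": "PE(14:0/14:0)",
    "PC": "PC(14:0/14:0)",
    "PI": "PC(14:0/14:0)",
}

#: RT windows are reported at 0.01-min resolution.
RT_RESOLUTION = 0.01


def ecn(species: PhospholipidSpecies | str) -> int:
    """Effective carbon number: sum of acyl carbons minus twice the double bonds.

    Oxygenation does not enter the ECN; oxygen effects are carried by the
    per-stratum calibration instead.
    """
    if isinstance(species, str):
        species = parse_species(species)
    carbons = sum(a.carbons for a in species.acyls)
    double_bonds = sum(a.double_bonds for a in species.acyls)
    return carbons - 2 * double_bonds


@dataclass(frozen=True)
class ReferenceWindow:
    """A measured retention-time window for one (species, n[O])."""

    species: str
    oxygens: int
    t_min: float
    t_max: float

    def __post_init__(self) -> None:
        if not self.t_min < self.t_max:
            raise ValueError(
                f"reference window for {self.species} {self.oxygens}[O] needs t_min < t_max"
            )

    @property
    def centre(self) -> float:
        return 0.5 * (self.t_min + self.t_max)

    @property
    def half_width(self) -> float:
        return 0.5 * (self.t_max - self.t_min)


@dataclass
class _Stratum:
    slope: float
    intercept: float
    half_width: float
    references: list[ReferenceWindow] = field(default_factory=list)


class ECNCalibration:
    """Per-(headgroup, n[O]) linear retention model fitted to reference windows.

    Estimator-style object: ``fit(reference_windows)`` then
    ``predict(species, oxygens)`` -> (t_min, t_max). Fitted state lives in
    ``strata_`` keyed by (headgroup, oxygens).

    Parameters
    ----------
    default_slope : min per ECN unit used when neither the stratum nor the
        class's 0[O] calibration has two distinct ECN values to fit a slope.
        Must be positive (retention increases with ECN in reversed phase).
    headgroup_aliases : fallback mapping for classes without any reference of
        their own; by default PI borrows the PC calibration (the two classes
        form one analytical group sharing the DMPC normalization standard).
    """

    def __init__(
        self,
        default_slope: float = 0.08,
        headgroup_aliases: dict[str, str] | None = None,
    ) -> None:
        if default_slope <= 0:
            raise ValueError("default_slope must be > 0")
        self.default_slope = default_slope
        self.headgroup_aliases = {"PI": "PC"} if headgroup_aliases is None else dict(
            headgroup_aliases
        )

    def get_params(self, deep: bool = True) -> dict:
        return {
            "default_slope": self.default_slope,
            "headgroup_aliases": dict(self.headgroup_aliases),
        }

    def set_params(self, **params) -> "ECNCalibration":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, references: list[ReferenceWindow]) -> "ECNCalibration":
        if not references:
            raise ValueError("at least one reference window is required")
        grouped: dict[tuple[str, int], list[ReferenceWindow]] = {}
        for ref in references:
            hg = parse_species(ref.species).headgroup
            grouped.setdefault((hg, ref.oxygens), []).append(ref)

        # first pass: fit every stratum with >=2 distinct ECN values
        fitted: dict[tuple[str, int], _Stratum] = {}
        for key, refs in grouped.items():
            x = np.array([ecn(r.species) for r in refs], dtype=float)
            y = np.array([r.centre for r in refs])
            hw = max(r.half_width for r in refs)
            if len(np.unique(x)) >= 2:
                slope, intercept = np.polyfit(x, y, 1)
                if slope <= 0:
                    raise ValueError(
                        f"fitted slope for stratum {key} is non-positive ({slope:.4g}); "
                        "reference windows are inconsistent with reversed-phase elution"
                    )
                fitted[key] = _Stratum(float(slope), float(intercept), hw, refs)
        # second pass: single-ECN strata borrow a slope (0[O] of the class,
        # else any fitted stratum of the class, else the default)
        for key, refs in grouped.items():
            if key in fitted:
                continue
            hg, _ = key
            if (hg, 0) in fitted:
                slope = fitted[(hg, 0)].slope
            else:
                class_slopes = [s.slope for k, s in fitted.items() if k[0] == hg]
                slope = class_slopes[0] if class_slopes else self.default_slope
            x = np.array([ecn(r.species) for r in refs], dtype=float)
            y = np.array([r.centre for r in refs])
            intercept = float(np.mean(y - slope * x))
            hw = max(r.half_width for r in refs)
            fitted[key] = _Stratum(float(slope), intercept, hw, refs)

        self.strata_ = fitted
        self.references_ = list(references)
        return self

    # -- prediction --------------------------------------------------------

    def _stratum(self, headgroup: str, oxygens: int) -> _Stratum:
        if not hasattr(self, "strata_"):
            raise RuntimeError("calibration is not fitted; call fit() first")
        key = (headgroup, oxygens)
        if key in self.strata_:
            return self.strata_[key]
        alias = self.headgroup_aliases.get(headgroup)
        if alias is not None and (alias, oxygens) in self.strata_:
            return self.strata_[(alias, oxygens)]
        raise KeyError(
            f"calibration does not cover stratum (headgroup={headgroup}, oxygens={oxygens})"
        )

    def predict(
        self, species: PhospholipidSpecies | str, oxygens: int
    ) -> tuple[float, float]:
        """Predicted closed RT window [t_min, t_max] in minutes, 0.01-min grid."""
        if isinstance(species, str):
            species = parse_species(species)
        stratum = self._stratum(species.headgroup, oxygens)
        centre = stratum.slope * ecn(species) + stratum.intercept
        t_min = max(round(centre - stratum.half_width, 2), RT_RESOLUTION)
        t_max = round(centre + stratum.half_width, 2)
        return (t_min, t_max)

    def window_table(self, species_names: list[str], oxygen_levels: list[int]) -> pd.DataFrame:
        rows = []
        for name in species_names:
            for n in oxygen_levels:
                t_min, t_max = self.predict(name, n)
                rows.append(
                    {"species": name, "oxygens": n, "t_min": t_min, "t_max": t_max}
                )
        return pd.DataFrame(rows, columns=["species", "oxygens", "t_min", "t_max"])


def fit_ecn_calibration(
    references: list[ReferenceWindow], default_slope: float = 0.08
) -> ECNCalibration:
    """Functional wrapper over :class:`ECNCalibration`."""
    return ECNCalibration(default_slope=default_slope).fit(references)


def predict_rt_window(
    species: PhospholipidSpecies | str, oxygens: int, calibration: ECNCalibration
) -> tuple[float, float]:
    """Predicted retention-time window for a species at an oxygenation level."""
    return calibration.predict(species, oxygens)


def build_ox_transitions(
    species_names: list[str], oxygen_levels: list[int] = (1, 2, 3)
) -> pd.DataFrame:
    """MRM transition table for oxidized species.

    One transition per (species, n[O], oxidizable acyl): Q1 is the precursor
    under the class adduct ([M+OAc]- for PC, [M-H]- for PE/PI) shifted by the
    incorporated oxygens, Q3 the oxidized carboxylate anion. Only acyls with
    >=2 double bonds are oxidation targets; saturated/monounsaturated chains
    are not oxidized in this workflow, so fully SFA/MUFA species yield no
    transitions.
    """
    rows = []
    for name in species_names:
        sp = parse_species(name)
        adduct = class_adduct(sp.headgroup)
        for n in oxygen_levels:
            if n < 1:
                raise ValueError("oxygen levels must be >= 1")
            q1 = molecular_mass(sp.with_oxygens(sp.oxygens + n), adduct)
            seen: set[str] = set()
            for acyl in sp.acyls:
                if acyl.double_bonds < 2 or str(acyl) in seen:
                    continue
                seen.add(str(acyl))
                rows.append(
                    {
                        "species": name,
                        "oxygens": n,
                        "adduct": adduct.value,
                        "target_acyl": str(acyl),
                        "q1_mz": round(q1, 4),
                        "q3_mz": round(fragment_mz(acyl, n), 4),
                    }
                )
    return pd.DataFrame(
        rows, columns=["species", "oxygens", "adduct", "target_acyl", "q1_mz", "q3_mz"]
    )


def filter_signals_by_rt(
    signals: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Keep signals whose retention time lies inside the closed window of their
    (species, oxygens); signals without a window raise.

    ``signals`` needs columns sample_id, species, oxygens, intensity, rt_min;
    ``windows`` needs species, oxygens, t_min, t_max.
    """
    win = {
        (row.species, int(row.oxygens)): (float(row.t_min), float(row.t_max))
        for row in windows.itertuples()
    }
    keep = []
    for row in signals.itertuples():
        key = (row.species, int(row.oxygens))
        if key not in win:
            raise KeyError(f"no retention-time window for {key[0]} {key[1]}[O]")
        t_min, t_max = win[key]
        keep.append(t_min <= float(row.rt_min) <= t_max)
    return signals[np.array(keep, dtype=bool)].reset_index(drop=True)


def aggregate_oxidation(
    filtered: pd.DataFrame,
    annotations: pd.DataFrame,
    standard_signals: pd.DataFrame,
    expected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalized oxidized-species amounts per (sample, species, n[O]).

    value = (sum of surviving isomer signals) / class-standard signal / cell count

    When the signal table distinguishes transitions (a ``transition_id``
    column), only the most intense transition per (sample, species, n[O]) is
    quantified; its isomer peaks are then summed without discrimination.

    ``standard_signals`` holds one row per (sample_id, species) for the
    measured DMPC/DMPE standards (column ``intensity``). ``expected``
    optionally lists (sample_id, species, oxygens) combinations that must
    appear in the output; combinations with no surviving signal report 0.
    """
    ann = annotations.set_index("sample_id")
    std = standard_signals.set_index(["sample_id", "species"])["intensity"]
    if "transition_id" in filtered.columns and not filtered.empty:
        per_transition = (
            filtered.groupby(
                ["sample_id", "species", "oxygens", "transition_id"], sort=True
            )["intensity"]
            .sum()
            .reset_index()
        )
        best = per_transition.loc[
            per_transition.groupby(["sample_id", "species", "oxygens"])[
                "intensity"
            ].idxmax()
        ]
        sums = best.rename(columns={"intensity": "signal_sum"})[
            ["sample_id", "species", "oxygens", "signal_sum"]
        ]
    else:
        sums = (
            filtered.groupby(["sample_id", "species", "oxygens"], sort=True)["intensity"]
            .sum()
            .reset_index(name="signal_sum")
        )
    if expected is not None:
        have = set(zip(sums["sample_id"], sums["species"], sums["oxygens"]))
        extra = [
            {"sample_id": r.sample_id, "species": r.species, "oxygens": r.oxygens,
             "signal_sum": 0.0}
            for r in expected.itertuples()
            if (r.sample_id, r.species, r.oxygens) not in have
        ]
        if extra:
            extra_df = pd.DataFrame(extra)
            sums = extra_df if sums.empty else pd.concat([sums, extra_df], ignore_index=True)
        sums = sums.sort_values(["sample_id", "species", "oxygens"], ignore_index=True)
    rows = []
    for row in sums.itertuples():
        if row.sample_id not in ann.index:
            raise ValueError(f"sample {row.sample_id!r} missing from annotations")
        cells = ann.loc[row.sample_id].get("cell_count", np.nan)
        if pd.isna(cells) or cells <= 0:
            raise ValueError(f"cell count missing or non-positive for {row.sample_id!r}")
        hg = parse_species(row.species).headgroup
        std_name = OX_NORMALIZATION_STANDARD[hg]
        try:
            std_signal = float(std.loc[(row.sample_id, std_name)])
        except KeyError:
            raise ValueError(
                f"standard {std_name!r} not measured in sample {row.sample_id!r}"
            ) from None
        if std_signal <= 0:
            raise ValueError(f"standard signal is zero for {std_name!r} in {row.sample_id!r}")
        rows.append(
            {
                "sample_id": row.sample_id,
                "species": row.species,
                "oxygens": int(row.oxygens),
                "amount_per_cell": row.signal_sum / std_signal / float(cells),
            }
        )
    return pd.DataFrame(
        rows, columns=["sample_id", "species", "oxygens", "amount_per_cell"]
    )
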