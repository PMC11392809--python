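"""Tab-separated interchange formats.

One dialect everywhere: UTF-8, tab-separated, mandatory header row, ``.`` for
missing values, species in shorthand nomenclature. Floats are written with
``%.10g`` so repeated runs produce byte-identical files.

Tables
------
signals.tsv    sample_id, species, fragment_id, intensity, rt_min
samples.tsv    sample_id, group, [timepoint_h], replicate, [protein_mg], [cell_count]
standards.tsv  species, amount_nmol
windows.tsv    species, oxygens, t_min, t_max
expression.tsv genes x samples (first column = gene id)
gene sets      GMT (see :mod:`pufascope.sigscore`)
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .lipids import parse_species
from .oxident import ReferenceWindow

__all__ = [
    "default_reference_windows",
    "read_expression",
    "read_reference_windows",
    "read_signals",
    "read_samples",
    "read_standards",
    "write_table",
]

NA_REP = "."
FLOAT_FORMAT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy frame in the interchange dialect, deterministically."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(
        path,
        sep="\t",
        index=False,
        na_rep=NA_REP,
        float_format=FLOAT_FORMAT,
        lineterminator="\n",
    )


def _read(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=True, **kwargs)


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _validate_species_column(df: pd.DataFrame, path) -> None:
    for row_no, name in enumerate(df["species"], start=2):  # header is line 1
        try:
            parse_species(str(name))
        except ValueError as exc:
            raise ValueError(f"{path}, row {row_no}: {exc}") from None


def read_signals(path) -> pd.DataFrame:
    df = _read(path)
    _check_columns(df, ("sample_id", "species", "fragment_id", "intensity"), path)
    _validate_species_column(df, path)
    return df


def read_samples(path) -> pd.DataFrame:
    df = _read(path)
    _check_columns(df, ("sample_id", "group"), path)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id entries")
    return df


def read_standards(path) -> pd.DataFrame:
    df = _read(path)
    _check_columns(df, ("species", "amount_nmol"), path)
    _validate_species_column(df, path)
    return df


def read_reference_windows(path) -> list[ReferenceWindow]:
    df = _read(path)
    _check_columns(df, ("species", "oxygens", "t_min", "t_max"), path)
    _validate_species_column(df, path)
    return [
        ReferenceWindow(str(r.species), int(r.oxygens), float(r.t_min), float(r.t_max))
        for r in df.itertuples()
    ]


def default_reference_windows() -> list[ReferenceWindow]:
    """The shipped measured reference windows (oxidized PC/PE(16:0/20:4))."""
    ref = resources.files("pufascope").joinpath("data/reference_windows.tsv")
    with resources.as_file(ref) as path:
        return read_reference_windows(path)


def read_expression(path) -> pd.DataFrame:
    df = _read(path, index_col=0)
    df.index.name = "gene"
    return df
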