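"""Gene-signature scoring: epithelial–mesenchymal (EM) positioning and ssGSEA.

Two single-sample scores position tumour expression profiles on the
epithelial–mesenchymal spectrum and quantify signature activity:

* **EM score** — a signed two-sample Kolmogorov–Smirnov statistic comparing
  the within-sample expression distribution of a mesenchymal gene set against
  an epithelial gene set. The score is the larger one-sided KS deviation with
  its sign: positive when the mesenchymal set's expression stochastically
  dominates. It is bounded in [-1, 1] and invariant under any strictly
  increasing transform of the sample's values.

* **ssGSEA** — a weighted running-sum enrichment score: genes are ranked by
  expression (descending); the score integrates the difference between the
  in-set cumulative fraction, weighted by |value|^alpha, and the uniform
  out-of-set cumulative fraction. At alpha = 0 the score is purely
  rank-based. The default exponent alpha = 0.25 follows the single-sample
  GSEA convention.

Convention: samples ordered by ascending EM score run epithelial (left) to
mesenchymal (right); the MUFA signature is {SCD, FASN}, the PUFA signature
{FADS2, ELOVL5, ACSL4}, and ZEB1 scores as a singleton set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "em_score",
    "order_by_em",
    "read_gmt",
    "scale_matrix",
    "score_samples",
    "ssgsea_score",
    "write_gmt",
]

#: Lipogenic-enzyme signatures used alongside the EM score.
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "MUFA": ("SCD", "FASN"),
    "PUFA": ("FADS2", "ELOVL5", "ACSL4"),
    "ZEB1": ("ZEB1",),
}


class GeneSignature:
    """A named, non-empty gene set."""

    def __init__(self, name: str, genes) -> None:
        genes = tuple(dict.fromkeys(genes))  # de-duplicate, keep order
        if not genes:
            raise ValueError(f"gene signature {name!r} is empty")
        self.name = name
        self.genes = genes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSignature({self.name!r}, {len(self.genes)} genes)"


def _validate_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
    if expr.shape[0] < 2 or expr.shape[1] < 1:
        raise ValueError("expression matrix needs >=2 genes and >=1 sample")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression values must be finite")
    return expr


def scale_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across samples (mean 0, population s.d. 1).

    Constant genes have no scale and are dropped with a logged warning.
    Idempotent up to numerical precision.
    """
    expr = _validate_matrix(expr)
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant gene(s) before scaling", int(constant.sum()))
        expr = expr.loc[~constant]
        values = values[~constant]
        sd = sd[~constant]
    centred = values - values.mean(axis=1, keepdims=True)
    return pd.DataFrame(centred / sd[:, None], index=expr.index, columns=expr.columns)


def em_score(
    sample: pd.Series, epithelial: GeneSignature, mesenchymal: GeneSignature
) -> float:
    """Signed KS statistic between mesenchymal- and epithelial-set expression.

    Positive when mesenchymal genes sit higher in the sample's expression
    distribution. Missing genes are ignored; if either set has no measured
    gene the score is NaN.
    """
    mes = sample.reindex(mesenchymal.genes).dropna().to_numpy(dtype=float)
    epi = sample.reindex(epithelial.genes).dropna().to_numpy(dtype=float)
    if mes.size == 0 or epi.size == 0:
        log.warning("EM score undefined: empty measured gene set")
        return float("nan")
    # signed two-sample KS: max deviation of F_epi - F_mes over all data points
    grid = np.concatenate([mes, epi])
    f_mes = np.searchsorted(np.sort(mes), grid, side="right") / mes.size
    f_epi = np.searchsorted(np.sort(epi), grid, side="right") / epi.size
    diff = f_epi - f_mes  # positive where mesenchymal values dominate above t
    d_plus = diff.max()
    d_minus = (-diff).max()
    return float(d_plus if d_plus >= d_minus else -d_minus)


def ssgsea_score(
    sample: pd.Series, signature: GeneSignature, alpha: float = 0.25
) -> float:
    """Weighted running-sum single-sample enrichment score.

    Genes are ranked by value descending (ties broken by gene id for
    determinism). The score is the sum over ranked positions of the
    difference between the |value|^alpha-weighted in-set cumulative fraction
    and the uniform out-of-set cumulative fraction.
    """
    values = sample.to_numpy(dtype=float)
    genes = np.asarray(sample.index)
    in_set = np.isin(genes, np.asarray(signature.genes, dtype=genes.dtype))
    if not in_set.any():
        raise ValueError(f"no gene of signature {signature.name!r} is measured")
    if in_set.all():
        raise ValueError(f"signature {signature.name!r} covers every measured gene")
    # descending by value, ascending by gene id on ties
    order = np.lexsort((genes, -values))
    values = values[order]
    in_set = in_set[order]
    weights = np.where(in_set, np.abs(values) ** alpha, 0.0)
    w_total = weights.sum()
    if w_total == 0:  # all in-set values are exactly zero: fall back to ranks
        weights = in_set.astype(float)
        w_total = weights.sum()
    cdf_in = np.cumsum(weights) / w_total
    cdf_out = np.cumsum(~in_set) / (len(values) - in_set.sum())
    return float(np.sum(cdf_in - cdf_out))


def score_samples(
    expr: pd.DataFrame,
    epithelial: GeneSignature,
    mesenchymal: GeneSignature,
    signatures: dict[str, GeneSignature] | None = None,
    alpha: float = 0.25,
    scale_for_em: bool = True,
    scale_for_ssgsea: bool = False,
) -> pd.DataFrame:
    """EM score plus per-signature ssGSEA scores for every sample.

    EM scoring follows the scaled-matrix convention; ssGSEA runs on raw
    values by default (both toggleable).
    """
    expr = _validate_matrix(expr)
    if signatures is None:
        signatures = {
            name: GeneSignature(name, genes) for name, genes in DEFAULT_SIGNATURES.items()
        }
    em_matrix = scale_matrix(expr) if scale_for_em else expr
    ss_matrix = scale_matrix(expr) if scale_for_ssgsea else expr
    rows = []
    for sample_id in expr.columns:
        row = {"sample_id": sample_id}
        row["em_score"] = em_score(em_matrix[sample_id], epithelial, mesenchymal)
        for name, sig in signatures.items():
            row[f"ssgsea_{name}"] = ssgsea_score(ss_matrix[sample_id], sig, alpha=alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def order_by_em(scores: pd.DataFrame) -> pd.DataFrame:
    """Samples sorted ascending by EM score (epithelial -> mesenchymal).

    Ties are broken by sample id so the ordering is deterministic.
    """
    return scores.sort_values(
        ["em_score", "sample_id"], kind="stable", ignore_index=True
    )


def read_gmt(path) -> dict[str, GeneSignature]:
    """Read gene sets from GMT (name, description, tab-separated gene ids)."""
    sets: dict[str, GeneSignature] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line {line_no}: needs name, desc, >=1 gene")
            name = fields[0]
            sets[name] = GeneSignature(name, [g for g in fields[2:] if g])
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(signatures: dict[str, GeneSignature], path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in signatures:
            genes = "\t".join(signatures[name].genes)
            fh.write(f"{name}\t{description}\t{genes}\n")
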