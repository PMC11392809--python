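"""End-to-end orchestration: quantify -> oxident -> stats, and signature runs.

A run is driven by a validated :class:`RunConfig` (unknown keys rejected) and
writes a bundle of tidy TSV tables plus ``manifest.json`` carrying the config
hash, package and library versions, the seed and the SHA-256 of every output
file. Identical config + inputs reproduce the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io, oxident, quantify, sigscore, stats

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_lipidomics", "run_signatures"]


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    signals: str | None = None
    samples: str | None = None
    standards: str | None = None
    ox_signals: str | None = None
    ox_standard_signals: str | None = None
    reference_windows: str | None = None  # None -> shipped measured windows
    expression: str | None = None
    gene_sets: str | None = None
    epithelial_set: str = "epithelial"
    mesenchymal_set: str = "mesenchymal"
    contrasts: list[dict] = field(default_factory=list)
    fdr_level: float = 0.05
    equal_variance: bool = True
    log2_epsilon: float | None = None
    ecn_default_slope: float = 0.08
    ssgsea_alpha: float = 0.25
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if not 0 < cfg.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        for contrast in cfg.contrasts:
            for key in ("treatment", "vehicle"):
                if key not in contrast:
                    raise ValueError(f"contrast {contrast} is missing {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, config: RunConfig, outputs: list[Path]) -> Path:
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "pufascope_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": json.loads(config_json),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-18s %.2fs", name, t1 - t0)
    return t1


def run_lipidomics(config: RunConfig, out_dir) -> dict[str, Path]:
    """Composition, ox-amount, percent-change and volcano tables plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failure_marker = out / "FAILED"
    failure_marker.write_text("run did not complete\n")
    outputs: list[Path] = []
    t0 = time.perf_counter()
    try:
        if not (config.signals and config.samples):
            raise ValueError("lipidomics run needs 'signals' and 'samples' inputs")
        signals = io.read_signals(config.signals)
        samples = io.read_samples(config.samples)
        standards = io.read_standards(config.standards) if config.standards else None
        t0 = _stage("load", t0)

        comp = quantify.compute_composition(signals, standards)
        for name, frame in (
            ("relative_intensities.tsv", comp.relative),
            ("acyl_shares.tsv", comp.acyl_shares),
            ("class_fractions.tsv", comp.fractions),
            ("category_proportions.tsv", comp.categories),
        ):
            io.write_table(frame, out / name)
            outputs.append(out / name)
        t0 = _stage("composition", t0)

        amounts = None
        if standards is not None:
            amounts = quantify.absolute_amounts(signals, samples, standards)
            io.write_table(amounts, out / "amounts.tsv")
            outputs.append(out / "amounts.tsv")
        t0 = _stage("amounts", t0)

        if config.ox_signals:
            ox_signals = pd.read_csv(config.ox_signals, sep="\t")
            ox_std = pd.read_csv(config.ox_standard_signals, sep="\t")
            calibration = oxident.ECNCalibration(
                default_slope=config.ecn_default_slope
            ).fit(
                io.read_reference_windows(config.reference_windows)
                if config.reference_windows
                else io.default_reference_windows()
            )
            windows = calibration.window_table(
                sorted(ox_signals["species"].unique()),
                sorted(int(n) for n in ox_signals["oxygens"].unique()),
            )
            io.write_table(windows, out / "windows.tsv")
            outputs.append(out / "windows.tsv")
            kept = oxident.filter_signals_by_rt(ox_signals, windows)
            ox_amounts = oxident.aggregate_oxidation(kept, samples, ox_std)
            io.write_table(ox_amounts, out / "oxamounts.tsv")
            outputs.append(out / "oxamounts.tsv")
        t0 = _stage("oxident", t0)

        if amounts is not None:
            for contrast in config.contrasts:
                tag = contrast.get("name") or f"{contrast['treatment']}_vs_{contrast['vehicle']}"
                timepoint = contrast.get("timepoint")
                pct = quantify.percent_change_vs_vehicle(
                    amounts, samples, contrast["treatment"], contrast["vehicle"], timepoint
                )
                io.write_table(pct, out / f"percent_change_{tag}.tsv")
                outputs.append(out / f"percent_change_{tag}.tsv")
                vol = stats.volcano(
                    amounts,
                    samples,
                    (contrast["treatment"], contrast["vehicle"]),
                    timepoint=timepoint,
                    fdr_level=config.fdr_level,
                    equal_variance=config.equal_variance,
                    epsilon=config.log2_epsilon,
                )
                io.write_table(vol, out / f"volcano_{tag}.tsv")
                outputs.append(out / f"volcano_{tag}.tsv")
        t0 = _stage("stats", t0)

        manifest = _write_manifest(out, config, outputs)
        outputs.append(manifest)
    except Exception:
        raise
    else:
        failure_marker.unlink()
    return {p.name: p for p in outputs}


def run_signatures(config: RunConfig, out_dir) -> dict[str, Path]:
    """EM and ssGSEA scores per sample, ordered along the EM spectrum."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.expression:
        raise ValueError("signature run needs an 'expression' input")
    expr = io.read_expression(config.expression)
    if config.gene_sets:
        sets = sigscore.read_gmt(config.gene_sets)
    else:
        raise ValueError("signature run needs a 'gene_sets' GMT input")
    for required in (config.epithelial_set, config.mesenchymal_set):
        if required not in sets:
            raise ValueError(f"gene set {required!r} not found in {config.gene_sets}")
    signatures = {
        name: sig
        for name, sig in sets.items()
        if name not in (config.epithelial_set, config.mesenchymal_set)
    }
    scores = sigscore.score_samples(
        expr,
        epithelial=sets[config.epithelial_set],
        mesenchymal=sets[config.mesenchymal_set],
        signatures=signatures or None,
        alpha=config.ssgsea_alpha,
    )
    ordered = sigscore.order_by_em(scores)
    io.write_table(ordered, out / "scores.tsv")
    manifest = _write_manifest(out, config, [out / "scores.tsv"])
    return {"scores.tsv": out / "scores.tsv", "manifest.json": manifest}
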