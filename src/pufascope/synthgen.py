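"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the study designs the analysis operates on, so every
stage can run and be validated without external data:

* :func:`generate_lipidome` — per-class MRM species intensities for two cell
  states ("Zeb1-high" mesenchymal vs "Zeb1-low" epithelial) with log-normal
  replicate noise, dual acyl-fragment records per species, spiked deuterated
  internal standards (0.2 nmol each) and per-sample protein mass. The default
  scenario programs a noise-free PE PUFA:MUFA ratio of 1.5 in the Zeb1-high
  group versus 0.75 in the Zeb1-low group, n = 6 replicates per group and a
  15% coefficient of variation.
* :func:`generate_ox_timecourse` — a GPX4-inhibitor-style (RSL3) time course
  of oxidized-species signals placed at their true retention times with
  Gaussian jitter, decoy signals placed 0.5 min outside every window, a flat
  vehicle arm, and DMPC/DMPE standards with cell counts for normalization.
* :func:`generate_expression` — a genes x samples matrix with a programmed
  epithelial->mesenchymal gradient: mesenchymal and PUFA-signature genes
  shift up along the gradient, epithelial and MUFA-signature genes shift
  down, on a Gaussian background.

A single root seed fans out to named substreams so each generator is
independently reproducible; every ground-truth record carries the programmed
quantities needed to validate recovery without rerunning the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import parse_species
from .quantify import fa_distribution

__all__ = [
    "ExpressionScenario",
    "LipidomeScenario",
    "OxTimecourseScenario",
    "default_expression_scenario",
    "default_lipidome_scenario",
    "default_ox_scenario",
    "generate_expression",
    "generate_lipidome",
    "generate_ox_timecourse",
]

#: Spiked amount of each internal standard, in nmol.
IS_AMOUNT_NMOL = 0.2

_SUBSTREAMS = {"lipidome": 0, "timecourse": 1, "expression": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[stream],)))


# ---------------------------------------------------------------------------
# lipidome
# ---------------------------------------------------------------------------


@dataclass
class LipidomeScenario:
    """Two-group lipidome design with per-group noise-free species intensities.

    ``group_abundances`` maps group -> species -> baseline intensity (cps).
    Replicate intensities are baseline x LogNormal(mu=-s^2/2, s) with s chosen
    so the multiplicative noise has coefficient of variation ``cv`` and mean 1
    (unbiased). Internal standards per class are spiked at fixed signal
    levels; protein mass is constant across samples.
    """

    group_abundances: dict[str, dict[str, float]]
    n_per_group: int = 6
    cv: float = 0.15
    is_signals: dict[str, float] = field(
        default_factory=lambda: {
            "PE(15:0/18:1-d7)": 2000.0,
            "PI(15:0/18:1-d7)": 1500.0,
            "PC(15:0/18:1-d7)": 2500.0,
        }
    )
    is_amount_nmol: float = IS_AMOUNT_NMOL
    protein_mg: float = 0.1
    cell_count: int = 1_000_000
    fragment_split: float = 0.2  # fragments at I*(1 +/- split); their mean is I
    # shared per-sample intensity factor (extraction/injection variability);
    # multiplies every signal incl. the spiked standards, so composition
    # metrics and IS-normalized amounts are invariant to it
    sample_scale_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        for group, abundances in self.group_abundances.items():
            for sp, a in abundances.items():
                if a <= 0:
                    raise ValueError(f"abundance must be > 0 ({group}, {sp})")


def default_lipidome_scenario() -> LipidomeScenario:
    """Zeb1-high vs Zeb1-low PE/PI panels with programmed PUFA:MUFA 1.5 vs 0.75."""
    # PE panel: 18:0_20:4 feeds PUFA (half) + SFA (half); 18:1/18:1 feeds MUFA;
    # 16:0/16:0 feeds SFA. Ratios: high 30/20 = 1.5, low 24/32 = 0.75.
    pe_high = {"PE(18:0_20:4)": 6000.0, "PE(18:1/18:1)": 2000.0, "PE(16:0/16:0)": 2000.0}
    pe_low = {"PE(18:0_20:4)": 4800.0, "PE(18:1/18:1)": 3200.0, "PE(16:0/16:0)": 2000.0}
    # PI panel with the protective PI(18:1/18:1) lipokine enriched in the low group
    pi_high = {"PI(18:0_20:4)": 1500.0, "PI(18:1/18:1)": 500.0, "PI(16:0/18:1)": 500.0}
    pi_low = {"PI(18:0_20:4)": 700.0, "PI(18:1/18:1)": 1200.0, "PI(16:0/18:1)": 600.0}
    return LipidomeScenario(
        group_abundances={
            "Zeb1-high": {**pe_high, **pi_high},
            "Zeb1-low": {**pe_low, **pi_low},
        }
    )


def _lognormal_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _truth_composition(abundances: dict[str, float]) -> dict:
    """Programmed per-class composition implied by noise-free abundances."""
    by_class: dict[str, dict[str, float]] = {}
    for name, value in abundances.items():
        by_class.setdefault(parse_species(name).headgroup, {})[name] = value
    out: dict[str, dict] = {}
    for hg, species in by_class.items():
        total = sum(species.values())
        rel = pd.DataFrame(
            {"species": list(species), "rel_pct": [100.0 * v / total for v in species.values()]}
        )
        _, fracs = fa_distribution(rel)
        ratio = fracs["PUFA"] / fracs["MUFA"] if fracs["MUFA"] else float("nan")
        out[hg] = {
            "rel_pct": dict(zip(rel["species"], rel["rel_pct"])),
            "fractions": fracs,
            "pufa_mufa_ratio": ratio,
        }
    return out


def generate_lipidome(
    scenario: LipidomeScenario, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """(signals, sample annotations, standards, ground truth) for a lipidome run."""
    rng = _rng(seed, "lipidome")
    signal_rows, sample_rows = [], []
    for group in sorted(scenario.group_abundances):
        abundances = scenario.group_abundances[group]
        species_names = sorted(abundances)
        for rep in range(1, scenario.n_per_group + 1):
            sample_id = f"{group}_r{rep}"
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "replicate": rep,
                    "protein_mg": scenario.protein_mg,
                    "cell_count": scenario.cell_count,
                }
            )
            scale = _lognormal_noise(rng, scenario.sample_scale_cv, 1)[0]
            noise = _lognormal_noise(rng, scenario.cv, len(species_names))
            for name, eps in zip(species_names, noise):
                intensity = abundances[name] * eps * scale
                sp = parse_species(name)
                split = scenario.fragment_split
                for tag, frag_intensity in (
                    ("fa1", intensity * (1 + split)),
                    ("fa2", intensity * (1 - split)),
                ):
                    acyl = sp.acyls[0 if tag == "fa1" else 1]
                    signal_rows.append(
                        {
                            "sample_id": sample_id,
                            "species": name,
                            "fragment_id": f"{tag}:{acyl}",
                            "intensity": frag_intensity,
                            "rt_min": 5.0,
                        }
                    )
            # spike internal standards (two identical acyl fragments); they share
            # the per-sample scale factor, which the normalization cancels
            for is_name, is_signal in sorted(scenario.is_signals.items()):
                for tag in ("fa1", "fa2"):
                    signal_rows.append(
                        {
                            "sample_id": sample_id,
                            "species": is_name,
                            "fragment_id": f"{tag}",
                            "intensity": is_signal * scale,
                            "rt_min": 5.0,
                        }
                    )
    signals = pd.DataFrame(signal_rows)
    samples = pd.DataFrame(sample_rows)
    standards = pd.DataFrame(
        {
            "species": sorted(scenario.is_signals),
            "amount_nmol": [scenario.is_amount_nmol] * len(scenario.is_signals),
        }
    )
    truth = {
        "groups": {
            group: _truth_composition(abund)
            for group, abund in scenario.group_abundances.items()
        },
        "n_per_group": scenario.n_per_group,
        "cv": scenario.cv,
        "seed": seed,
    }
    return signals, samples, standards, truth


# ---------------------------------------------------------------------------
# oxidized time course
# ---------------------------------------------------------------------------


@dataclass
class OxTimecourseScenario:
    """RSL3-style induction of oxidized species with decoys outside RT windows.

    True retention windows follow a linear ECN model with per-n[O] intercepts
    mimicking the measured non-monotone oxygen dependence (2[O] slightly later
    than 1[O], 3[O] much earlier). ``induction`` maps species -> n[O] ->
    timepoint (h) -> fold over baseline in the treated arm; vehicle stays
    flat.
    """

    species: tuple[str, ...] = ("PE(18:0_20:4)", "PC(16:0/20:4)")
    oxygen_levels: tuple[int, ...] = (1, 2, 3)
    timepoints_h: tuple[float, ...] = (0.5, 1.0, 2.0)
    baseline_signal: float = 500.0
    induction: dict = field(
        default_factory=lambda: {
            "PE(18:0_20:4)": {3: {0.5: 1.5, 1.0: 2.5, 2.0: 4.0}},
        }
    )
    n_per_group: int = 3
    cv: float = 0.20
    rt_jitter_sd: float = 0.0
    decoy_offset_min: float = 0.5
    slope: float = 0.08  # min per ECN unit
    intercepts: dict = field(default_factory=lambda: {0: 1.2, 1: 0.7, 2: 0.8, 3: -0.6})
    half_width: float = 0.15
    standard_signal: float = 1000.0
    cell_count: int = 1_000_000

    def true_centre(self, species: str, oxygens: int) -> float:
        from .oxident import ecn

        return self.slope * ecn(species) + self.intercepts[oxygens]

    def true_window(self, species: str, oxygens: int) -> tuple[float, float]:
        c = self.true_centre(species, oxygens)
        return (c - self.half_width, c + self.half_width)

    def reference_windows(self) -> pd.DataFrame:
        """True windows for every (species, n[O]) incl. 0[O], for calibration."""
        rows = []
        for name in self.species:
            for n in (0, *self.oxygen_levels):
                t_min, t_max = self.true_window(name, n)
                rows.append({"species": name, "oxygens": n, "t_min": round(t_min, 4),
                             "t_max": round(t_max, 4)})
        return pd.DataFrame(rows)


def default_ox_scenario() -> OxTimecourseScenario:
    return OxTimecourseScenario()


def generate_ox_timecourse(
    scenario: OxTimecourseScenario, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """(ox signals, sample annotations, standard signals, truth) for a time course."""
    rng = _rng(seed, "timecourse")
    signal_rows, sample_rows, std_rows = [], [], []
    for group in ("Veh", "RSL3"):
        for t in scenario.timepoints_h:
            for rep in range(1, scenario.n_per_group + 1):
                sample_id = f"{group}_t{t:g}_r{rep}"
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "group": group,
                        "timepoint_h": t,
                        "replicate": rep,
                        "cell_count": scenario.cell_count,
                    }
                )
                for std_name in ("PE(14:0/14:0)", "PC(14:0/14:0)"):
                    std_rows.append(
                        {
                            "sample_id": sample_id,
                            "species": std_name,
                            "intensity": scenario.standard_signal,
                        }
                    )
                for name in scenario.species:
                    for n in scenario.oxygen_levels:
                        fold = 1.0
                        if group == "RSL3":
                            fold = scenario.induction.get(name, {}).get(n, {}).get(t, 1.0)
                        eps = _lognormal_noise(rng, scenario.cv, 1)[0]
                        intensity = scenario.baseline_signal * fold * eps
                        centre = scenario.true_centre(name, n)
                        jitter = (
                            rng.normal(0.0, scenario.rt_jitter_sd)
                            if scenario.rt_jitter_sd > 0
                            else 0.0
                        )
                        rt = max(centre + jitter, 0.01)
                        signal_rows.append(
                            {
                                "sample_id": sample_id,
                                "species": name,
                                "oxygens": n,
                                "transition_id": "t1",
                                "intensity": intensity,
                                "rt_min": rt,
                                "decoy": False,
                            }
                        )
                        # decoy outside the window by a fixed offset
                        t_min, t_max = scenario.true_window(name, n)
                        signal_rows.append(
                            {
                                "sample_id": sample_id,
                                "species": name,
                                "oxygens": n,
                                "transition_id": "t1",
                                "intensity": intensity * 0.5,
                                "rt_min": t_max + scenario.decoy_offset_min,
                                "decoy": True,
                            }
                        )
    truth = {
        "induction": scenario.induction,
        "baseline_signal": scenario.baseline_signal,
        "windows": {
            f"{name}|{n}": scenario.true_window(name, n)
            for name in scenario.species
            for n in scenario.oxygen_levels
        },
        "seed": seed,
    }
    return (
        pd.DataFrame(signal_rows),
        pd.DataFrame(sample_rows),
        pd.DataFrame(std_rows),
        truth,
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass
class ExpressionScenario:
    """Expression matrix with a programmed epithelial->mesenchymal gradient.

    Sample ``j`` has EM position t_j on [-1, 1]; mesenchymal-set genes get a
    mean shift of +em_effect x t_j, epithelial genes the opposite; the PUFA
    signature genes shift with +sig_effect x t_j, the MUFA genes with
    -sig_effect x t_j and ZEB1 with +sig_effect x t_j, on Normal(0, noise_sd)
    background noise.
    """

    n_genes: int = 500
    n_samples: int = 60
    n_set_genes: int = 10
    em_effect: float = 2.0
    sig_effect: float = 1.5
    noise_sd: float = 1.0

    def positions(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.n_samples)

    def gene_sets(self) -> dict[str, tuple[str, ...]]:
        # synthetic placeholder epithelial/mesenchymal sets; the real KS
        # signature lists are user-supplied via GMT in production use
        epithelial = tuple(f"EPI{i:02d}" for i in range(1, self.n_set_genes + 1))
        mesenchymal = tuple(f"MES{i:02d}" for i in range(1, self.n_set_genes + 1))
        return {
            "epithelial": epithelial,
            "mesenchymal": mesenchymal,
            "MUFA": ("SCD", "FASN"),
            "PUFA": ("FADS2", "ELOVL5", "ACSL4"),
            "ZEB1": ("ZEB1",),
        }


def default_expression_scenario() -> ExpressionScenario:
    return ExpressionScenario()


def generate_expression(
    scenario: ExpressionScenario, seed: int
) -> tuple[pd.DataFrame, dict[str, tuple[str, ...]], dict]:
    """(genes x samples matrix, gene sets, truth) with a programmed EM gradient."""
    rng = _rng(seed, "expression")
    sets = scenario.gene_sets()
    special = [g for name in ("epithelial", "mesenchymal", "MUFA", "PUFA", "ZEB1")
               for g in sets[name]]
    n_background = scenario.n_genes - len(special)
    if n_background < 0:
        raise ValueError("n_genes smaller than the signature genes")
    genes = special + [f"BG{i:04d}" for i in range(1, n_background + 1)]
    samples = [f"S{j:03d}" for j in range(1, scenario.n_samples + 1)]
    positions = scenario.positions()

    values = rng.normal(0.0, scenario.noise_sd, size=(len(genes), len(samples)))
    shift = np.zeros((len(genes), 1))
    direction = {
        "epithelial": -scenario.em_effect,
        "mesenchymal": scenario.em_effect,
        "MUFA": -scenario.sig_effect,
        "PUFA": scenario.sig_effect,
        "ZEB1": scenario.sig_effect,
    }
    gene_index = {g: i for i, g in enumerate(genes)}
    for set_name, effect in direction.items():
        for g in sets[set_name]:
            shift[gene_index[g], 0] = effect
    values = values + shift * positions[None, :]
    expr = pd.DataFrame(values, index=genes, columns=samples)
    truth = {
        "positions": dict(zip(samples, positions.tolist())),
        "direction": direction,
        "seed": seed,
    }
    return expr, sets, truth
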