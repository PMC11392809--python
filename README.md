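# pufascope

Targeted phospholipidomics analysis for studying how membrane lipid
composition shapes ferroptosis sensitivity, plus the gene-signature scoring
used to place tumour expression profiles on the epithelial–mesenchymal (EM)
spectrum.

Ferroptosis — iron-dependent cell death by peroxidation of membrane
phospholipids — requires polyunsaturated fatty acyls (PUFAs) in those
phospholipids, while monounsaturated acyls (MUFAs) are protective. The
read-out that matters is therefore the **PUFA:MUFA ratio** of the
phosphatidylcholine (PC), -ethanolamine (PE) and -inositol (PI) pools, and
the abundance of **oxidized species** such as PE(18:0_20:4 + 3[O]).
`pufascope` turns targeted MRM (multiple-reaction-monitoring) signal tables
into exactly these quantities, for analysts working with QTRAP-style
negative-mode lipidomics exports and for anyone reproducing such analyses on
synthetic data.

## What it computes

* **Nomenclature and masses** (`pufascope.lipids`) — parses shorthand diacyl
  species names (`PE(18:0_20:4 + 3[O])`, `PI(15:0/18:1-d7)`), classifies
  acyls (SFA: 0 double bonds, MUFA: 1, PUFA: ≥2), and computes monoisotopic
  precursor m/z under the class adducts ([M−H]⁻ for PE/PI, [M+OAc]⁻ for PC)
  and oxidized carboxylate fragment m/z ([FA + n·O − H]⁻).
* **Quantification** (`pufascope.quantify`) — per-species signal as the mean
  of the two fatty acid anion fragments; absolute amounts
  `signal / IS_signal × IS_nmol / protein_mg` against the class-specific
  deuterated internal standard; per-class relative intensities (Σ = 100%);
  the fatty-acyl decomposition (each species contributes half its intensity
  to each acyl) giving SFA/MUFA/PUFA fractions and the PUFA:MUFA ratio;
  PUFA-containing vs SFA/MUFA-only category split; percent change and fold
  change against vehicle.
* **Oxidized-species identification** (`pufascope.oxident`) — MRM transitions
  for 1–3 incorporated oxygens, retention-time windows predicted by an
  effective-carbon-number model (ECN = ΣC − 2·ΣDB, window centre linear in
  ECN per (class, n[O]) stratum, anchored on measured oxPAPC and
  oxPE(16:0/20:4) windows), closed-interval RT filtering, and isomer-summed
  amounts normalized to DMPC/DMPE and cell number.
* **Statistics** (`pufascope.stats`) — unpaired two-tailed t-tests and the
  adaptive two-stage linear step-up FDR (stage 1 at q/(1+q) estimates the
  null fraction m₀/m; stage 2 steps up at q·m/m₀) feeding per-panel volcano
  tables; viability normalization and SYTOX death rates.
* **Signature scoring** (`pufascope.sigscore`) — the signed two-sample
  Kolmogorov–Smirnov EM score (positive = mesenchymal) and ssGSEA
  (|value|^α-weighted running sum, α = 0.25) for the MUFA ({SCD, FASN}),
  PUFA ({FADS2, ELOVL5, ACSL4}) and ZEB1 signatures.
* **Synthetic data** (`pufascope.synthgen`) — seeded generators for two-state
  lipidomes (programmed PE PUFA:MUFA 1.5 vs 0.75, n = 6, CV 15%), oxidized
  time courses with RT decoys, and expression matrices with a programmed
  E→M gradient.

## Worked example

```sh
pufascope synthgen --scenario lipidome --seed 1 --out demo
pufascope quantify --signals demo/signals.tsv --samples demo/samples.tsv \
    --standards demo/standards.tsv --out demo/out
head -4 demo/out/class_fractions.tsv
```

```text
sample_id	headgroup	sfa_pct	mufa_pct	pufa_pct	pufa_mufa_ratio
Zeb1-high_r1	PE	48.84066022	23.24381958	27.9155202	1.200986787
Zeb1-high_r1	PI	38.53775601	30.97139475	30.49084924	0.9844842145
Zeb1-high_r2	PE	52.1730453	16.53449768	31.29245702	1.892555651
```

Each row is one sample × class: the acyl-level SFA/MUFA/PUFA percentages
(summing to 100) and their PUFA:MUFA ratio. Summarizing the PE pool per group
(mean fractions across the n = 6 replicates, then the ratio of means):

```python
import pandas as pd
from pufascope import io, quantify

frac = pd.read_csv("demo/out/class_fractions.tsv", sep="\t")
samples = io.read_samples("demo/samples.tsv")
print(quantify.group_mean_fractions(frac[frac.headgroup == "PE"], samples))
```

```text
    group headgroup   sfa_pct  mufa_pct  pufa_pct  pufa_mufa_ratio
Zeb1-high        PE 50.993498 18.348279 30.658223         1.670904
 Zeb1-low        PE 41.712122 35.285022 23.002855         0.651916
```

The mesenchymal-state ("Zeb1-high") PE pool is PUFA-enriched and the
epithelial-state pool MUFA-enriched, around the programmed ratios of 1.5 and
0.75 (single-experiment estimates scatter with the 15% replicate CV). The
`volcano_*.tsv` outputs of `pufascope run` add per-species log2 fold changes
with two-stage-FDR q values; `pufascope oxident` writes predicted RT windows
(`windows.tsv`) and normalized oxidized-species amounts (`oxamounts.tsv`);
`pufascope sigscore` writes per-sample EM and signature scores ordered along
the EM spectrum.

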