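# Methods

This note documents the models, conventions and numerical choices behind
`pufascope`, what the synthetic generators do and do not emulate, and the
known limitations.

## Lipid model

Species are diacyl glycerophospholipids of the PC, PE and PI classes, written
in shorthand: `HG(C1:D1 SEP C2:D2 [+ n[O]])` with `SEP` either `/`
(sn-positions asserted) or `_` (unresolved). The oxygen annotation is
accepted inside or after the parentheses and canonicalized to the inside
form, which is how such species are printed in targeted-lipidomics outputs.
Acyls carry optional `Δn` double-bond-position notes and `-dk` deuterium
labels. Two deliberate conventions:

* **Δ-positions are display metadata.** `PE(18:1Δ6/18:1Δ9)` and
  `PE(18:1Δ9/18:1Δ9)` are distinct species for reporting (they distinguish
  desaturase products) but positional isomers are isobaric, so masses are
  identical.
* **`+ n[O]` is a formula-level oxygen count.** Oxidized species are
  quantified without discriminating hydroxy/hydroperoxy/epoxy regio- and
  stereoisomers, so the model deliberately does not assign regiochemistry;
  n ∈ {1, 2, 3} is in scope.

Masses are assembled as glycerophospho-headgroup backbone + two fatty acids −
2 H₂O (+ n oxygens, with each deuterium adding m(²H) − m(¹H)), from a frozen
monoisotopic constants table (`_masses.py`) so that reported m/z values do
not drift with dependency upgrades. Adducts follow the negative-mode class
rule (PE/PI → [M−H]⁻; PC → [M+OAc]⁻); fragment m/z is the (oxidized)
carboxylate anion. The test suite cross-checks ≥20 species against a
pyteomics atomic-mass-sum oracle built from different building blocks
(glycerol + phosphoric acid + head alcohol − 4 H₂O); agreement is required to
1 mDa. Ether and lyso lipids are rejected explicitly: the quantification
rules below (two acyl fragments, half/half decomposition) are only meaningful
for diacyl species.

## Quantification

* **Species signal** = arithmetic mean of the recorded fatty acid anion
  fragments (two for a diacyl species; one tolerated).
* **Absolute amounts** (nmol per mg protein) =
  `signal / IS_signal × IS_amount / protein_mass`, with the class-specific
  deuterated standard (PC/PE/PI(15:0/18:1-d7), spiked at 0.2 nmol) as IS.
  Absolute output for PC is flagged as an extension in the result table: the
  established absolute read-out covers PE and PI.
* **Internal standards** are auto-detected by deuterium label, plus anything
  listed in the standards table (covers non-deuterated DMPC/DMPE); they are
  excluded from every composition metric.
* **Relative intensities** are percentages of the per-(sample, class) sum.
  **Acyl decomposition** gives each species' two acyls half its relative
  intensity each, irrespective of sn-assignment (the decomposition is
  symmetric, which is why `/` and `_` species are treated identically
  downstream); sums over unsaturation classes give the SFA/MUFA/PUFA
  fractions, and PUFA%/MUFA% is the PUFA:MUFA ratio. A class with neither
  PUFA nor MUFA reports ratio 0; PUFA present with zero MUFA reports a
  missing ratio with a warning.
* **Group summaries** average replicate fractions first and then take the
  ratio of means (`group_mean_fractions`) — the convention behind
  mean-composition pie/radar summaries, and a lower-variance estimator than
  averaging per-replicate ratios.
* **Replicate aggregation** for percent change and fold change uses
  arithmetic means of per-replicate values; per-replicate outputs feed the
  statistics. Log2 fold changes floor zero means at a configurable epsilon
  (default: smallest positive observed amount × 10⁻³) and log a warning for
  affected species.

## Oxidized-species identification

Transitions pair the class-adduct precursor (shifted by n oxygens) with the
oxidized carboxylate fragment of each oxidizable acyl; only acyls with ≥2
double bonds are oxidation targets. When several transitions exist for one
(species, n[O]), quantification uses the most intense one per sample.

Retention windows come from an effective-carbon-number model,
ECN = ΣC − 2·ΣDB — the standard reversed-phase retention predictor (each
double bond costs roughly two methylenes of retention). Within a
(headgroup, n[O]) stratum the window centre is linear in ECN with a positive
slope; the half-width is the largest reference half-width in the stratum.
Design choices:

* **Per-stratum intercepts, not a single oxygen term.** The measured
  reference windows are non-monotone in n[O] (for the same backbone, 2[O]
  elutes slightly later than 1[O] while 3[O] elutes much earlier), which a
  single additive per-oxygen shift cannot represent.
* **Slope borrowing.** The shipped reference file contains one backbone per
  stratum (oxPAPC = oxidized PC(16:0/20:4) at 1–3[O]; oxidized PE(16:0/20:4)
  at 1–2[O]), so no slope is identifiable from it alone. A stratum with <2
  distinct ECN values borrows the slope from the class's 0[O] calibration,
  then from any fitted stratum of the class, then falls back to a
  configurable default of 0.08 min per ECN unit — a mid-gradient figure for
  short reversed-phase lipid gradients; with single-reference strata the
  model then interpolates through the reference point and reproduces its
  window exactly, so the default only matters for extrapolation to other
  backbones.
* **PI aliases to PC** by default: the two classes are handled as one
  analytical group (both normalized to DMPC), and no PI ox-reference exists.
* **Windows are closed intervals** on a 0.01-min grid; boundary signals are
  kept (conservative inclusion, consistent with windows that were widened to
  catch regioisomers).

Surviving signals per (sample, species, n[O]) are summed over isomer peaks
and normalized to the class standard signal (DMPE for PE, DMPC for PC/PI) and
the cell count.

## Statistics

Two-sample comparisons use the pooled-variance Student t-test by default
(Welch via flag). The multiple-testing correction is the adaptive two-stage
linear step-up procedure: stage 1 is a Benjamini–Hochberg step-up at
q′ = q/(1+q) whose rejection count r₁ estimates the true-null count
m₀ = m − r₁; stage 2 is a step-up at q·m/m₀. If stage 1 rejects nothing the
procedure reduces to plain BH at q; if m₀ = 0 everything is rejected. Because
m/m₀ ≥ 1 the procedure always rejects a superset of BH at the same q.
Reported q-values are the stage-2 step-up adjusted values scaled by m₀/m, so
`q ≤ level` reproduces the rejection decision exactly. Ties in p are resolved
by a stable (p, species) sort for bit-for-bit reproducible tables.

Volcano t-tests run on **log2-transformed amounts** by default: MS intensity
noise is multiplicative, so the equal-variance assumption holds on the log
scale (raw-scale testing is available via `on_log_scale=False`). Correction
is applied per figure panel — one class and contrast at a time — with the
panel defined by the run configuration.

Viability readings are normalized to the control mean (= 100%); death rate is
SYTOX-positive object count per confluence percent, missing (with a warning)
at zero confluence.

## Signature scoring

The EM score is a signed two-sample Kolmogorov–Smirnov statistic between the
within-sample expression of a mesenchymal and an epithelial gene set: the
larger one-sided ECDF deviation, signed positive when the mesenchymal set
stochastically dominates. It is bounded in [−1, 1], invariant under strictly
increasing transforms of the sample, and antisymmetric under set exchange.
EM scoring operates on the per-gene z-scored matrix (constant genes dropped
with a warning); samples are ordered ascending, epithelial → mesenchymal.

ssGSEA is the integrated running-sum form: genes ranked by value descending
(ties broken by gene id), score = Σᵢ (weighted in-set CDF − uniform out-set
CDF) with weights |value|^α, α = 0.25 by default (the single-sample GSEA
convention); α = 0 makes the score purely rank-based. No cross-set
renormalization is applied, and ssGSEA runs on raw values by default with
scaling available by flag. The packaged epithelial/mesenchymal demonstration
sets are synthetic placeholders; real KS signature lists are supplied via
GMT. The lipogenic-enzyme signatures are MUFA = {SCD, FASN},
PUFA = {FADS2, ELOVL5, ACSL4} and the ZEB1 singleton.

## Synthetic data

One root seed fans out to named substreams (lipidome / timecourse /
expression), so each generator is reproducible independently of the others.

* **Lipidome**: two cell states with noise-free per-species intensities whose
  implied PE PUFA:MUFA ratios are 1.5 ("Zeb1-high") and 0.75 ("Zeb1-low");
  n = 6 replicates per group; per-species log-normal noise with CV 15%
  (mean-1, so programmed compositions are unbiased); a shared per-sample
  log-normal scale factor (CV 20%) emulating extraction/injection
  variability, which also multiplies the spiked standards — composition
  metrics and IS-normalized amounts are invariant to it, which is precisely
  what internal standards are for; two acyl fragments per species whose mean
  equals the drawn intensity.
* **Oxidized time course**: a GPX4-inhibition-style arm with a programmed
  induction of PE(18:0_20:4) + 3[O] (1.5× / 2.5× / 4× at 0.5 / 1 / 2 h)
  against a flat vehicle arm, n = 3, CV 20%; signals placed at the true RT of
  a linear ECN model with per-n[O] intercepts mimicking the measured
  non-monotone oxygen dependence; one decoy per signal placed 0.5 min outside
  its window; DMPC/DMPE standards and cell counts included.
* **Expression**: 500 genes × 60 samples with programmed EM positions on
  [−1, 1]; mesenchymal/PUFA/ZEB1 genes shift up along the gradient and
  epithelial/MUFA genes down (effect sizes 2.0 / 1.5 s.d. units) on unit
  Gaussian background noise.

What the generators do **not** emulate: chromatographic peak shapes and
integration, isotope envelopes, missing values and censoring at the detection
limit, between-batch drift, correlated biological covariation between
species, and real signature gene lists. Passing recovery tests therefore
demonstrates that the arithmetic, filtering and inference chain is correct
under the stated noise model — not that the pipeline is robust to every
artefact of real acquisitions.

## Problem sizes and tolerances

Validation uses 100 random samples for conservation checks (tolerance 1e−9 on
sums, 1e−12 against the slot-enumeration oracle), 10,000 random p-vectors
(m ≤ 12) for the FDR definition check, 1000 null panels for the FDR level,
40 simulated experiments for PUFA:MUFA recovery (Monte-Carlo mean within 10%;
a single experiment's estimator has ≈8% relative standard error at n = 6 /
CV 15%, so one-draw assertions would conflate luck with correctness), 200
simulations for volcano power on the 4× induction, and 1000 permutations for
the EM null. Masses agree with the independent oracle to 1 mDa; everything
runs in well under a minute on one CPU except the power simulation (a few
seconds per hundred runs).

## Known limitations

* Diacyl PC/PE/PI only; ether/lyso/other classes are rejected, not modelled.
* The ECN default slope (0.08 min/ECN) is a stand-in wherever references
  cannot identify a slope; predictions extrapolated with it carry that
  uncertainty and should be re-anchored with user reference windows when
  available.
* The two-stage FDR is the q·m/m₀ stage-2 variant (always at least as
  powerful as BH); its null behaviour is verified by simulation rather than
  inherited from the q′-both-stages proof.
* ssGSEA scores are not normalized across gene sets; comparisons are within a
  signature across samples, not between signatures.
* Absolute quantification assumes equal response factors between each species
  and its class internal standard.
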