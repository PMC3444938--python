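# silacdyn

Proteome dynamics and metabolite label tracing for pulsed-SILAC
experiments in slow-growing phototrophs such as *Chlamydomonas
reinhardtii*.

When an arginine-auxotroph culture is switched to ¹³C₆-arginine, every
newly made protein is heavy and every pre-existing protein is light, so a
protein's heavy/light (H/L) intensity ratio reports its synthesis over
the pulse. `silacdyn` turns MaxQuant-style protein-group tables and
MetMax-style GC-MS fragment tables into:

- **growth-corrected protein half-lives.** Under exponential growth
  (doubling time T_double) with first-order decay of the light pool,
  R(t) = e^(k_loss·t) − 1 with k_loss = k_deg + k_dil and
  k_dil = ln 2 / T_double. The loss rate is fit per protein by
  through-origin least squares of ln(1 + R) on t (with the implicit
  (0 h, 0) anchor), the dilution rate is subtracted, and
  T½ = ln 2 / k_deg. Proteins synthesised more slowly than biomass
  accumulates (k_deg ≤ 0) are censored, never given negative half-lives.
- **relative abundance.** The abundance index AI = intensity /
  molecular mass for intra-sample ranking and stoichiometry (e.g. the
  rbcL:rbcS RuBisCO subunit ratio), with emPAI = 10^(PAI) − 1 as the
  reference alternative and reproducibility statistics on a known
  dilution series.
- **salt-stress synthesis responses.** Per-condition Z-normalisation of
  log2 H/L ratios at the comparison time point, selection of the shared
  upper/lower responder tails across salt conditions, and Spearman rank
  concordance between conditions.
- **percent ¹³C label in metabolites.** For declared GC-MS fragment
  pairs (e.g. proline 142/146), label % = 100 · (H/L − H/L of the
  unlabeled control), which subtracts the natural ¹³C background;
  intensities are normalised by internal standard and cell number.
- **a seeded synthetic-data generator** producing all of the above
  inputs with known ground truth, so every estimator is testable without
  the original mass-spectrometry data.

## Worked example

Simulate a study-style experiment (three salt conditions, duplicate
cultures, doubling time 63.41 h, half-life median 45 h) and estimate
half-lives back:

```bash
silacdyn simulate --seed 7 --out-dir demo
silacdyn turnover --proteins demo/protein_groups.tsv \
                  --metadata demo/metadata.yaml --out demo/fits.tsv
```

prints

```
n_ok: 705
n_censored: 0
n_insufficient: 5
median_h: 41.693357189102585
q1_h: 29.640802945850723
q3_h: 60.985058966681095
median_defined: true
t_double_h: 63.4099999999988
expected_ratio_24h: 0.29997979231321814
```

`t_double_h` is recovered from the simulated cell counts (1.3-fold
growth in 24 h ⇒ 63 h doubling time); `expected_ratio_24h` is the H/L
ratio a never-degraded protein would show after 24 h (0.30 — anything
above it indicates real turnover). 705 of 710 proteins pass the
quantification filters (ratio present, ≥ 3 ratio counts, ≥ 2 unique
peptides) at ≥ 2 time points; the recovered cohort median of 41.7 h sits
near this seed's true cohort median (the 710 half-lives are themselves a
random draw around 45 h). Per-protein fits are in `demo/fits.tsv`.

Metabolite label incorporation from the same simulation:

```bash
silacdyn label --metabolites demo/metabolite_table.tsv \
               --metadata demo/metadata.yaml --out demo/label.tsv
```

```
metabolite  sample_id  percent_label       fragment_spread  flagged
putrescine  lab_r1     4.654738874696588   0.9211383551556453  False
proline     lab_r1     10.533861571772135  0.0                 False
```

Proline was simulated at 10% label over a 5% natural-abundance
background; control subtraction recovers 10.5% in this replicate.
`fragment_spread` is the disagreement between a metabolite's fragment
pairs; large spread flags a contaminated fragment.

`silacdyn run --config config.yaml` chains growth → turnover →
abundance → stress → labeling on real tables and writes per-stage TSVs
plus `report.yaml`.

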