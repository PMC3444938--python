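# Methods

## Kinetic model

A pulsed-SILAC experiment in an arginine-auxotroph culture makes every
protein synthesised after t = 0 heavy. Assuming (i) balanced exponential
growth, P(t) = P₀·2^(t/T_double); (ii) first-order decay of the
pre-existing light pool; and (iii) complete heavy-arginine incorporation
into new protein, the light pool decays as e^(−k_loss·t) with
k_loss = k_deg + k_dil, where k_dil = ln 2 / T_double is the apparent
loss caused purely by growth dilution and k_deg is true proteolysis.
At steady state the heavy/light ratio is

    R(t) = e^(k_loss·t) − 1,

so ln(1 + R) is linear in t through the origin. Two consequences anchor
the analysis: a never-degraded protein (k_deg = 0) shows
R(t) = 2^(t/T_double) − 1 — the *expected ratio*, 0.30 at 24 h for the
63.4 h doubling time implied by 1.3-fold growth — and any protein above
that curve is genuinely turning over.

## Estimation

**Growth.** With two cell counts the growth factor is their plain ratio;
with more, a log-linear least-squares fit (the endpoint ratio is what the
original analysis used; the fit variant is reported alongside it).
T_double = window / log2(factor) is kept at full precision internally and
rounded to whole hours only for display. Cultures with factor ≤ 1 get an
infinite doubling time and k_dil = 0 rather than an error.

**Loss rate.** k_loss minimises Σᵢ (ln(1+Rᵢ) − k·tᵢ)², i.e.
k̂ = Σtᵢyᵢ / Σtᵢ². The (0 h, 0) anchor lies on every through-origin line
and is implicit. Regressing ln(1+R) rather than R is exact under the
model above and coincides with the plain linear fit for small R; the
raw-R variant is available (`--use-linear-ratio`) for comparison.
Time points 3, 8 and 24 h are used by default; the 1 h point is excluded
because the free arginine pool has not fully equilibrated that early.
Replicate cultures are pooled into one regression per protein.

**Half-life.** T½ = ln 2 / k_deg with k_deg = k_loss − k_dil. Ratio
noise can push slow proteins to k_deg ≤ 0; anything below
ε = 10⁻⁶ h⁻¹ (a half-life cap of ~7·10⁵ h) is reported as censored
with k_deg retained, and the cohort median is taken over non-censored
fits only — censored proteins are counted, never imputed. Proteins are
admitted per time point with the quantification-confidence filters
(ratio present, ratio count ≥ 3, unique peptides ≥ 2); fewer than two
usable points yields `insufficient_data`.

**Abundance.** AI = summed intensity / molecular mass, ranked within a
sample with deterministic protein-id tie-breaks. The summed (H+L)
intensity is the default since AI is an intra-sample measure; light- or
heavy-only channels can be selected when the input provides them.
Averaging across time points is an arithmetic mean ± SD. emPAI uses
observed / observable peptides, the latter counted as fully tryptic
7–30-mers when sequences are supplied.

**Stress comparison.** H/L ratios at the comparison time point (24 h)
are Z-transformed per condition on the log2 scale with the sample-SD
(n−1) convention. Log-scale Z-normalisation is invariant to any
condition-wide multiplicative bias — this is what absorbs the ratio
underestimation caused by partial metabolic conversion of labeled
arginine into proline/glutamate, without an explicit isotope-impurity
correction (a raw-scale variant exists behind `--z-raw`). Responders are
selected on the shift Δz = z_salt − z_control: the up (down) set is the
intersection of the top (bottom) floor(fraction·n) proteins across all
salt conditions, over the proteins shared by every condition, with
lexicographic tie-breaks. Concordance between salt conditions is
Spearman's rank correlation (ties mid-ranked).

**Metabolite labeling.** Percent label = 100·(H/L − H_c/L_c), the
heavy/light fragment ratio minus its mean over unlabeled controls
(natural ¹³C background is time-invariant, so 0 h samples are the
default controls). Note the H/L convention: a pool whose molecules are
9.09% heavy reads as 10%. Multi-fragment metabolites are aggregated by
unweighted mean; per-fragment values are always emitted and a
max−min spread above 5 percentage points flags discordant fragments.
The built-in fragment pairs are putrescine (4TMS) 86/87, 100/101,
174/175; proline (2TMS) 142/146; glutamate (3TMS) 84/85, 100/101,
156/157, 246/248; ornithine (3TMS) 174/175 — the run-on "100/101/174/175"
and comma-separated "174,175" in the source material are read as the
standard slash-separated pairs. Mass shifts never exceed 6 (the carbons
arginine can donate). Pool-size comparisons divide raw intensities by
internal standard × cell count; fold changes are log2 treated/control.

## Synthetic data

The generator emulates the study conditions: doubling time 63.41 h
(1.3-fold growth in 24 h), sampling of two independently grown cultures
at 1, 3, 8 and 24 h, half-lives drawn log-normally with median 45 h and
geometric SD 1.8 (right-skewed, consistent with proteome-wide turnover
surveys; the true dispersion in this organism is unknown and this is a
labeled modeling choice), 15% multiplicative ratio noise, ratio counts
1 + Poisson(3), and salt conditions modeled as scaled growth
(growth_scale·k_dil) plus a global synthesis scale, with optional
per-protein multipliers for planted responders. The dilution series puts
8 proteins at each of 6 ten-fold levels with true AI equal to the
concentration; the isotopomer generator emits light = base·noise and
heavy = light·(background + label)·noise with unlabeled controls.

Multiplicative noise is log-normal with **median 1**: factors
e^(N(0, s)) with s = √ln(1+cv²), so the coefficient of variation is
exactly cv while medians — the recovery estimands — stay unbiased.

What the generator does *not* emulate: peptide-level sampling and shared
peptides, missing-not-at-random ratios (missingness here is independent
of abundance), arginine-pool equilibration kinetics at early times,
arginine→proline interconversion bias (an optional global bias term can
probe the Z-normalisation's robustness to it), chromatographic artifacts
and isotope envelopes. Passing recovery tests therefore demonstrates
estimator correctness under the stated kinetic model, not robustness to
every pathology of real LC-MS data.

## Numerical choices and problem sizes

- Through-origin slope computed in closed form; residual is the exact
  minimised sum of squares. Tests cross-check against a 10⁻⁶-step grid
  minimizer.
- Censoring threshold ε = 10⁻⁶ h⁻¹; display rounding of T_double to
  whole hours; all internal arithmetic at float64 precision.
- TSV dialect is strict: tab-separated, dot decimal, no quoting;
  embedded tabs are rejected loudly. Missing ratios round-trip as empty
  cells (NaN accepted on read) and are never imputed.
- Test and acceptance runs use cohorts of 20–710 proteins and 6–12
  replicate GC-MS samples — sizes at which the median-recovery and
  label-recovery checks are statistically informative while the full
  suite completes in well under a minute of compute per file.
- The median of a 710-protein log-normal cohort (geometric SD 1.8) has
  ~±1.2 h sampling noise of its own; recovery checks therefore fix the
  generator seed.

## Known limitations

- One regression per protein; no per-time-point half-life tabulation by
  default, no Bayesian or ODE-based turnover models, no correction for
  the heavy-arginine pool's equilibration kinetics.
- AI is relative within a sample; absolute units depend on the
  instrument and are not comparable across studies.
- The percent-label estimator uses single fragment pairs, not a full
  mass-isotopomer distribution correction matrix; it is exact only when
  the heavy fragment carries all label carbons.
- Raw spectra processing (peptide identification, FDR control,
  deconvolution) is out of scope; inputs are already-quantified tables.
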