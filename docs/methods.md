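# Methods

## Scope and data flow

The package estimates the contribution of three exposure routes — dermal
absorption, inadvertent hand-to-mouth ingestion, inhalation — to the
quasi-steady-state blood-lead concentration of workers handling
lead-contaminated metal cutting fluids (MCFs).  The pipeline is

1. **Wipe reduction** (`wipes`): pooled acid-wipe extract masses →
   blank-corrected, area-normalised, reference-corrected skin doses
   (µg cm⁻²) per worker × hand × site.
2. **Diffusion-cell reduction** (`franz`): terminal compartment assays of
   static Franz cells → per-area amounts, percent-of-applied, recovery and
   time-averaged diffusion rates per (MCF, exposure time).
3. **Exposure model** (`exposure`): mean skin dose and mean air
   concentration → route uptakes (µg day⁻¹) → blood-Pb increments
   (µg dl⁻¹) via the adult-lead-model biokinetic slope factor.
4. **Statistics** (`nonparametric`): blood–dose Spearman correlations with
   exact permutation p at small n, tie-corrected Kruskal–Wallis, Dunn's
   pairwise z.
5. A statsmodels-style surface (`model.LeadExposureModel` /
   `LeadExposureResults`) ties the stages together and renders reports.

## Wipe-dose reduction conventions

- Dose = max(0, extract − blank) / area.  Blank subtraction precedes area
  normalisation; negatives clamp to zero.  Marked areas default to 9 cm²
  (palm, wrist; 3 × 3 cm) and 2 cm² (index finger; 1 × 2 cm).
- One clean-reference value per worker (the masked little finger of the
  non-dominant hand) is subtracted from all six surfaces of that worker,
  again clamping at zero.  No per-hand reference exists in the sampling
  design.
- Censored values are replaced by LOD/√2.  The substitution is applied to
  blood Pb (one censored worker in the packaged study) and is available
  for wipes.
- The study mean skin dose is the unweighted arithmetic mean over all
  worker × hand × site values (42 in the packaged study).  Full precision
  is kept internally (6.5576 µg cm⁻², reported rounded as 6.5): feeding
  the rounded value forward would change the dermal uptake from 13.8 to
  13.7 µg day⁻¹.

## Diffusion-cell reduction conventions

- Exposed area is fixed at the apparatus value 0.64 cm² (9-mm orifice,
  rounded as reported, not π·0.45²) so per-area arithmetic matches the
  published table; it is configurable per run.
- Donor totals include the three 1-ml donor rinses; receptor totals
  include the 5-ml acid rinse.  Only this summation closes the noise-free
  balance.
- The applied dose per MCF is the mean of the triplicate t = 0 donor-matrix
  samples.
- Cells with pre-exposure TEWL ≥ 10 g m⁻² h⁻¹ fail the barrier-integrity
  gate and are excluded (logged), never imputed.
- The average diffusion rate is 1000 × receptor (µg cm⁻²) / time (h) — a
  time-averaged quantity from a single terminal receptor sample, not an
  instantaneous flux.
- The dermal absorbed fraction used by the exposure model is the
  across-MCF mean of the receptor percent-of-applied: 0.0019729 at 2 h and
  0.0037308 at 24 h for the packaged tables, matching the published
  0.00197/0.00374.  The scenario stores these as dimensionless fractions;
  a percent-vs-fraction reading differs by 100× and is the user's
  responsibility when overriding.
- The skin-reservoir comparison across exposure times is a plain
  Kruskal–Wallis over time groups (no pairing structure exists in the
  design), with the direction of group medians reported separately.

## Exposure model

Route uptakes are the products listed in the README.  Hand-to-mouth events
run over the whole 8-h shift at 2 events h⁻¹ with 24 % transfer per
contact and 20 % gastrointestinal absorption.  Conversion to blood lead is
PbB = U × BKSF × workdays/365 with BKSF = 0.4 µg dl⁻¹ per µg day⁻¹ and
220 workdays yr⁻¹; the annualization factor is the adult-lead-model
averaging convention and reproduces every published blood value (e.g.
8.4 × 0.4 × 220/365 = 2.03).  Background blood lead is deliberately
outside the model: outputs are exposure contributions only, so totals must
not be read as predicted absolute blood concentrations.

## Statistical conventions

- Midranks throughout; rank sums always n(n+1)/2.
- Spearman's rho is the Pearson correlation of midranks.  For n ≤ 9 the
  two-sided p-value is exact, enumerating all n! permutations of one rank
  vector (5 040 at n = 7, instantaneous); larger n uses the t
  approximation with n − 2 df.  For the packaged study this yields
  p = 14/5040 = 0.0028 (left hand) and 62/5040 = 0.0123 (right hand).
- Kruskal–Wallis uses the standard tie correction 1 − Σ(t³−t)/(N³−N);
  identical observations give H = 0, p = 1 rather than an error.
- Dunn's test adjusts two-sided normal p-values Bonferroni-style over the
  *tested* pairs (Holm and no adjustment are options).  Planned contrasts
  can be restricted via `pairs=`; the index-vs-wrist contrasts of the
  packaged study are significant at α = 0.05 on both hands when tested as
  the two planned comparisons, which is how the published figure stars are
  reproducible.  Testing all 15 pairs of the six site × hand groups
  Bonferroni-corrects the left-hand contrast past 0.05.

## Synthetic-data generator

`simulate` produces full studies with known ground truth:

- **Workers.** Per-site doses are lognormal with site geometric means
  16 / 6 / 1.6 µg cm⁻² (index / palm / wrist, the non-glove level), GSD 2,
  and a shared per-worker random effect carrying half the log-variance
  (intraclass correlation 0.5).  Glove users (5 of 7 by default) have all
  doses multiplied by 0.35.  These defaults give an expected cohort mean
  near the observed 6.5 µg cm⁻² with the observed site ordering.  Raw wipe
  extracts are built by inverting the reduction (dose × area + uniform
  reference contamination + blank), so the noise-free reduction round-trips
  exactly.  Blood Pb is generated *from the forward exposure model* on each
  worker's mean dose (dermal 24-h window) times lognormal noise (GSD 1.3),
  censored at 0.72 µg dl⁻¹ — circular by design: the pipeline's job is
  recovery, and the blood–dose association then has known sign.
- **Diffusion cells.** A two-compartment first-order chain
  donor → skin → receptor with closed-form kinetics; k_in = 4.4 × 10⁻³ h⁻¹
  and k_out = 2.5 × 10⁻⁵ h⁻¹ (k_out ≪ k_in) give a growing skin reservoir
  of ~10 % of applied at 24 h and a receptor fraction of order 10⁻⁵–10⁻⁴,
  matching the 24-h in-vitro column.  A single uptake rate cannot also
  match the fast 2-h skin accumulation (~4 % of applied); the simulator is
  calibrated to the 24-h balance and to the orders of magnitude, not to
  every time point.  Multiplicative lognormal measurement noise (CV 5 %)
  is applied per compartment; with CV 0 the balance closes exactly.
- **Air.** Lognormal with arithmetic moments matched to the requested
  (mean, sd); default 1.2 ± 1.1 µg m⁻³.

All draws come from one `numpy.random.default_rng(seed)` per call, so
datasets are bit-reproducible.  What the generator does **not** emulate:
within-shift dose accumulation kinetics, between-day blood-lead buildup,
wipe removal efficiency, left/right-hand asymmetries beyond the shared
worker effect, and open (non-conserving) mass balances — the real
diffusion-cell data show recoveries of 60–80 %, while the simulator
conserves mass by construction.  Passing recovery tests therefore
demonstrate internal consistency of the pipeline, not field accuracy.

## Numerical choices and known data quirks

- All computation at full precision; rounding is presentation-only and
  rounded values never feed back into computation.
- The permutation test counts |rho| ≥ |rho_obs| − 10⁻¹², guarding against
  float round-off in ties.
- A handful of published percent-of-applied values are truncations rather
  than roundings of the underlying ratio (e.g. 12.0/290 = 4.138 printed as
  4.13; 8.28/79.2 = 10.45 printed as 10.4), and two cells are not
  reproducible from the printed amounts at all (MCF 4 donor 4 h: 76.9
  recomputed vs 76.5 printed; MCF 4 receptor 24 h: 0.0063 recomputed vs
  0.002 printed).  The acceptance checks therefore compare donor/skin
  percents within 0.5 points and receptor percents within 0.005 points.
- Published per-MCF diffusion rates were evidently computed per replicate
  cell before averaging; they are not reproducible from the published mean
  receptor amounts (0.00248/2 h = 1.24, printed 0.97).  Only the
  across-MCF mean rates (0.78 / 0.41 / 0.11 ng cm⁻² h⁻¹) are reproduced,
  from the published per-MCF rates.
- The published route table mixes rounding conventions (16.27 printed as
  16.2, 3.33 as 3.34, 26.24 as 26.3), so reproduction checks allow one
  unit in the last printed digit.

## Limitations

- The slope-factor relation is the linear quasi-steady-state approximation
  of the EPA adult lead model; no multi-compartment biokinetics, no
  GSD-based percentile estimation.
- No Fickian permeability fitting (k_p, lag time): the in-vitro design has
  a single terminal receptor sample per cell, supporting only the
  time-averaged rate.
- Skin doses are treated as 2-h accumulated totals as measured; projecting
  to a full shift is outside the model and would scale the dermal and
  ingestion routes proportionally.
- With n = 7 workers every inferential result is fragile; the exact
  permutation tests are honest about this but cannot add power.
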