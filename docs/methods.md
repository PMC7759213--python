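# Methods

## The measurement model

The package analyzes sensitized-emission FRET between a donor fluorophore
(mCerulean-like, detected in a "Pacific Blue" channel under violet
excitation) and an acceptor (mVenus-like, "FITC" channel under blue
excitation) fused to the intracellular ends of a two-chain receptor.
Ligand-induced dimerization brings donor and acceptor within Förster
range, producing acceptor emission under donor excitation (the
"AmCyan"/DA channel). Because raw FRET-channel intensity scales with
expression, the per-cell (or per-pixel) statistic is the
expression-normalized

    NFRET = F_fret / sqrt(F_donor × F_acceptor)

computed on *compensated* intensities, and optionally rescaled linearly
between a negative control (separate cytosolic donor and acceptor, mean
mapped to 0) and a positive control (covalent donor–acceptor fusion, mean
mapped to 1). Treatment effects are reported as the ligand/vehicle fold
difference of arm means.

## Synthetic-data generator

The generator (`fretquant.synthdata`) emulates the assay so pipeline
outputs can be checked against ground truth. Per cell:

* expression scale ~ LogNormal(`expr_mu` = 0, `expr_sigma` = 1), spanning
  roughly two decades, as flow data for transiently co-transfected cells
  do; a Bernoulli(`p_transfected` = 0.5) draw marks transfected cells;
* donor, acceptor and marker amounts are `donor_rate` (1000 a.u.),
  `acceptor_rate` (1000) and `marker_rate` (800) times the scale;
* the complexed fraction follows a one-site saturating dose response
  `f = f_veh + (f_max − f_veh)·L/(L + EC50)` with defaults
  `f_veh` = 0.15, `f_max` = 0.55, `EC50` = 10 nM, ligand dose 100 nM —
  chosen so calibrated fold differences land in the few-fold range
  typical of receptor dimerization assays;
* complexes are `C = f·min(D, A)` (the scarcer partner limits pairing;
  no explicit mass-action stoichiometry is modeled);
* FRET efficiency is the Förster form `E = 1/(1 + (r/R0)^6)` of the
  ectodomain C-terminal displacement `r`, with `R0` = 50 Å — a
  configurable stand-in on the ~10 nm interaction scale of FRET; any
  strictly decreasing E(r) would serve, the Förster form is used for
  physical realism. A direct `efficiency_override` bypasses the distance
  model (used for the fusion positive control, `E_fusion` = 0.6);
* the four signal sources per cell are quenched donor emission `D − E·C`,
  acceptor `A`, sensitized emission `E·C`, and marker `R`; observed
  channels are `sources × mixing + autofluorescence`, then multiplied by
  log-normal detector noise (`noise_cv` = 0.1) and clipped at the
  saturation value. Autofluorescence is additive log-normal
  (median 50 a.u., log-sd 0.4) per channel. Poisson shot noise is
  omitted: intensities are arbitrary units, not photon counts;
* the default mixing carries the bleed-through fractions a = 0.15,
  b = 0.02, c = 0.05, d = 0.40 (donor bleeds strongly into the FRET
  channel, as a cyan donor under violet excitation does);
* doublets (10% of events) are merged cell pairs: fluorescence and FSC-A
  add, FSC-H stays at single-cell height, giving the singlet gate real
  doublets to remove;
* image fields place non-overlapping disk cells (radius 12 px) on an
  autofluorescent background; pixel intensities follow the same source
  model, are clipped, and by default quantized to 16-bit integers
  (`saturation_value` = 65535). Placement uses bounded rejection
  sampling and raises if the requested cells cannot fit;
* calibration beads are discrete subpopulations whose observed MFI is
  log-normal with mean `true_slope × reference_value` and CV `cv`.

All randomness flows through explicit integer seeds (derived seeds stay
below 2^31); identical configuration gives bitwise-identical output.
Brightness ratios and detector gains are not measured quantities —
the defaults above are documented choices, not fits.

What the generator does **not** emulate: receptor trafficking and
kinetics, optics (PSF, illumination flatfield, z-structure), photon
statistics, spectral variation of bleed-through with expression level,
cell-shape heterogeneity, and instrument drift. Passing tests therefore
demonstrate correctness of the computations under a faithful but
simplified measurement model, not robustness to every artifact of real
acquisitions.

## Flow pipeline conventions

* **Spillover estimation**: per single-fluorophore control, the
  coefficient into each off-channel is the origin-constrained
  least-squares slope of off-channel vs primary-channel intensity over
  autofluorescence-subtracted positive events (at least 100 required).
  Compensation multiplies each event's channel vector by the inverse
  matrix; negative compensated values are kept — they are legitimate
  noise around zero, and truncating them would bias means. Sensitized
  emission has no single-color control by construction (it *is* acceptor
  emission under donor excitation); its matrix row is the identity into
  the FRET channel.
* **Gating order** is fixed: cells → singlets → transfected →
  donor+/acceptor+ double positives. The cell gate keeps the densest
  75% of (FSC-A, SSC-A) events by 2-D histogram density (64 bins),
  standing in for a manual polygon (which can be applied instead by
  filtering upstream). The singlet gate keeps FSC-A/FSC-H ratios within
  ±15% of the population median. Positivity thresholds are the
  (1 − rate) linear-interpolation quantile of the matching negative
  control (rate 0.01 by default), applied strictly (>): the strict
  comparison caps re-inclusion at the stated rate even when quantized
  intensities tie at the threshold.
* **NFRET** is undefined where donor × acceptor ≤ 0 (possible after
  compensation); such cells are excluded from summaries, mirroring the
  exclusion of undefined pixels in the image pipeline.
* **Summaries** average per-cell NFRET within each biological replicate
  first, then across replicates (SEM across replicates; a pooled-cells
  alternative is available). With a single replicate the SEM is reported
  as 0. Fold differences carry the delta-method SE
  `F·sqrt((SE_L/μ_L)² + (SE_V/μ_V)²)`, cross-checked in the tests
  against a parametric bootstrap; the fold is flagged undefined when the
  vehicle mean is nonpositive.

## Image pipeline conventions

* Autofluorescence thresholds are the 99.9th percentile (linear
  interpolation) of pixels pooled across all vector-only fields, per
  channel. Masking zeroes pixels at or below the threshold and removes
  pixels at the saturation value in any channel from every downstream
  average; validity is an explicit boolean matrix, never a sentinel
  intensity. The strictly-above survivor rule bounds surviving
  background at ceil((N−1)·0.001) pixels; note this exceeds 0.1% of N by
  a fraction of a pixel when 0.1% of N is not an integer — a property of
  the interpolated-quantile definition itself.
* Bleed-through parameters are means of per-pixel ratios pooled across
  control fields, excluding zero denominators. The ratio estimator does
  not subtract residual in-cell autofluorescence, so control
  acquisitions should be bright relative to background (at the default
  brightness and a background ~50× dimmer, the bias is ≪1%; dim controls
  over strong background bias small coefficients noticeably).
* The corrected FRET intensity defaults to the **nested** three-cube
  form `Fc = I_DA − a(I_AA − c·I_DD) − d(I_DD − b·I_AA)`; the **flat**
  literal sum `I_DA − a·I_AA − c·I_DD − d·I_DD − b·I_AA` is available as
  an explicit variant and every output records which was used. The two
  agree exactly whenever b·c = 0. The nested form itself leaves a
  second-order residual `b·c·(a·I_A + d·I_Dq)` relative to the true
  sensitized signal (≈0.1% of the bleed-through terms at the default
  b = 0.02, c = 0.05); the tests assert this closed form.
* Pixel NFRET is defined where the pixel is valid, I_AA·I_DD > 0 and Fc
  is finite. The sample statistic pools defined pixels across fields
  (equal to the pixel-count-weighted mean of field means); the
  unweighted mean of field means is reported alongside. Any field count
  ≥ 1 is accepted and logged. Rendered maps use fixed, recorded color
  scales with masked pixels in flat gray, and identical inputs produce
  byte-identical files.

## Calibration and normalization conventions

* Bead subpopulations: 1-D k-means on log MFI with sorted-quantile
  initialization (deterministic); k defaults to the number of reference
  values supplied (6 for six-peak, 9 for nine-peak reagents). The
  calibration regresses MFI on reference value through the origin
  (slope = a.u. per molecule, used as a divisor); the inverse
  orientation is a different estimator and is not used. Background is
  subtracted from MFI *before* dividing by the slope.
* Luciferase: technical replicates are averaged per readout, the
  vector-only mean is subtracted per readout, firefly/renilla ratios are
  scaled by the reciprocal of the reporter-only mean (so that condition
  is exactly 1); wells with nonpositive background-subtracted renilla
  are flagged invalid rather than propagated.
* Western blots: per exposure, each usable band is a percent of the
  total of its kind, which cancels exposure gain exactly; flagged
  (non-detectable/saturated) bands drop that lane from that exposure
  only. Exposure flags are caller-supplied; no densitometric
  auto-flagging is attempted. The internal-control comparison is a
  plain division; no cross-blot renormalization is applied.
* The distance regression is ordinary least squares with the two-tailed
  t-test p-value for the slope; horizontal data returns slope 0 with
  R² defined as 0.

## Problem sizes

Simulated studies use 2,500 cells per flow sample (≈900–1,000 survive
the full gate hierarchy), three biological replicates per treatment arm,
ten 256×256 fields per imaging sample (25 cells each), and six bead
subpopulations × 500 events. Recovery checks use 10,000-event controls.
The masking-rate check uses ten 250×400 vector-only fields so the 0.1%
pixel budget is an integer (see the quantile note above). These sizes
give sub-percent Monte-Carlo error on the recovered coefficients while
keeping every analysis script and the full test suite in the
tens-of-seconds range.

## Known limitations

* The spillover model is linear; detector nonlinearity near saturation
  is handled only by clipping/removal, not modeled.
* The origin-constrained spillover slopes inherit a small attenuation
  (≈cv²) from multiplicative noise on the primary channel, and the
  faintest coefficients carry a few-percent sampling scatter at 10,000
  events under two-decade expression heterogeneity.
* Fold differences of calibrated NFRET are insensitive to FRET
  efficiency except through donor quenching; distance trends in the
  synthetic study are therefore driven by quenching, and their absolute
  slope depends on the chosen Förster radius.
* No cell segmentation is performed in images (statistics are over
  pixels, not cells), and FCS files are not read — event tables are CSV.
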