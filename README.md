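# fretquant

Quantification of receptor-chain association by Förster resonance energy
transfer (FRET), for synthetic-receptor engineers and anyone running
sensitized-emission FRET assays on a flow cytometer or a confocal
microscope. The package implements the full analysis chain — spillover
compensation, hierarchical gating, expression-normalized FRET, pixel-wise
image FRET with bleed-through correction, rainbow-bead fluorescence
calibration, and reporter/expression normalization — together with a
synthetic-data generator that emulates the measurement process with known
ground truth, so every stage is verifiable end to end without instrument
data.

## The statistics at the core

**Flow NFRET.** Per cell, with compensated fluorescence intensities in the
FRET (AmCyan), donor (Pacific Blue) and acceptor (FITC) channels,

    NFRET = AmCyan / sqrt(Pacific Blue × FITC)

which is invariant to the cell's overall expression level. NFRET is
calibrated linearly between a no-interaction negative control (maps to 0)
and a covalent donor–acceptor fusion positive control (maps to 1).
Ligand-induced association is reported as the fold difference
ligand / vehicle, with a first-order (delta-method) standard error.

**Image FRET.** Per pixel, from the DD/AA/DA channel matrices (donor-excite
donor-emit, acceptor-excite acceptor-emit, donor-excite acceptor-emit),
four bleed-through fractions are estimated on single-color control fields
as averaged ratios

    a = I_DA/I_AA,  b = I_DD/I_AA   (acceptor-only)
    c = I_AA/I_DD,  d = I_DA/I_DD   (donor-only)

and the corrected FRET intensity (nested three-cube form, default) is

    Fc = I_DA − a(I_AA − c·I_DD) − d(I_DD − b·I_AA),
    NFRET = Fc / sqrt(I_AA × I_DD)

Background pixels are suppressed at the 99.9th percentile of vector-only
fields; saturated pixels are removed from every average.

**Calibration and normalization.** Bead subpopulations of known MEFL are
found by 1-D k-means on log intensity and MFI is regressed on reference
values through the origin (the slope converts a.u. to molecules of
equivalent fluorophore). Dual-luciferase plates are normalized so the
reporter-only condition means exactly 1; western-blot lanes use
percent-of-total band intensities (gain-invariant across exposures)
relative to an internal control lane. The dependence of NFRET fold
difference on ectodomain C-terminal distance is summarized by ordinary
least squares.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/`. For example, the flow-FRET dose
response (`python analysis/02_flow_fret.py`) prints:

```
spillover coefficients (estimated vs true):
  a: 0.1489 vs 0.15 (-0.7%)
  b: 0.0202 vs 0.02 (+1.0%)
  c: 0.0508 vs 0.05 (+1.5%)
  d: 0.4025 vs 0.40 (+0.6%)
gating: 2500 events -> 1876 cells -> 1872 singlets (0.00% residual doublets)
dose response (calibrated NFRET, mean of 3 replicates):
 dose_nM  mean_calibrated_nfret   sem  n_cells  fold_vs_vehicle  fold_se
   0.000                  0.168 0.002     2819            1.000    0.019
   1.000                  0.220 0.001     2755            1.309    0.018
   3.000                  0.293 0.003     2855            1.738    0.028
  10.000                  0.456 0.004     2839            2.706    0.042
  30.000                  0.638 0.002     2751            3.790    0.051
 100.000                  0.766 0.004     2800            4.549    0.065
```

Reading: the four spillover coefficients estimated from single-color
controls land within ~1% of the generator's truth; the singlet gate
removes the simulated doublets; calibrated NFRET rises with rapalog dose
along a saturating curve (half-maximal near the configured 10 nM EC50),
and the 100 nM fold difference is 4.55 ± 0.06 over ~2800 gated cells per
arm. `analysis/05_distance_regression.py` then shows the fold difference
falling linearly with the ectodomain C-terminal distance of four
simulated receptor systems.

A `fretquant` command-line interface wraps the same library for file-based
use (`fretquant sim flow|images|beads`, `fretquant analyze
flow|images|beads|luciferase|western|distance-fit`).

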