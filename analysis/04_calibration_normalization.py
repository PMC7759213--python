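"""Bead calibration and reporter/expression normalization.

Identifies bead subpopulations, fits the origin-constrained MFI-vs-MEFL
conversion slope, converts a simulated reporter experiment to MEFLs with
a fold difference, and runs the dual-luciferase and western-blot
normalizations on constructed plates/tables. Writes results/quantnorm/.
"""

import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from shared import REFS, results_dir

from fretquant import io, quantnorm as qn, stats as st, synthdata as sd

out_dir = results_dir("quantnorm")

# --- bead calibration ---------------------------------------------------
beads = sd.simulate_bead_set(REFS, true_slope=2.0, cv=0.05, n_per_subpop=500, seed=0)
mfis = qn.identify_bead_subpops(beads, k=6)
cal = qn.fit_bead_slope(mfis, REFS)
pd.DataFrame({"reference_mefl": REFS, "subpop_mfi": mfis}).to_csv(
    out_dir / "bead_calibration.csv", index=False
)
print(f"beads: slope {cal.slope:.4f} ± {cal.slope_se:.4f} a.u./MEFL "
      f"(true 2.0, {100 * (cal.slope / 2 - 1):+.2f}%)")

# --- reporter summary in MEFLs -----------------------------------------
rng = np.random.default_rng(1)
arm_mfis = {"ligand": (3000 + 150 * rng.standard_normal(3)).tolist(),
            "vehicle": (400 + 30 * rng.standard_normal(3)).tolist()}
autofl = (100 + 5 * rng.standard_normal(3)).tolist()
arms, fold = qn.reporter_summary(arm_mfis, autofl, cal)
pd.DataFrame([vars(m) for m in arms.values()]).to_csv(
    out_dir / "reporter_mefl.csv", index=False
)
print(f"reporter: ligand {arms['ligand'].mefl:.0f} MEFL, vehicle "
      f"{arms['vehicle'].mefl:.0f} MEFL, fold {fold.value:.2f} ± {fold.se:.2f}")
boot = st.bootstrap_fold_se(arms["ligand"].mefl, arms["ligand"].se,
                            arms["vehicle"].mefl, arms["vehicle"].se, seed=1)
print(f"  delta-method fold SE {fold.se:.3f} vs bootstrap {boot:.3f}")

# --- dual-luciferase plate ---------------------------------------------
plate = pd.DataFrame(
    {
        "condition": ["vector_only"] * 3 + ["reporter_only"] * 3 + ["receptor"] * 3,
        "firefly_1": [52.0, 48.0, 50.0, 950.0, 1030.0, 980.0, 4900.0, 5100.0, 5050.0],
        "firefly_2": [50.0, 51.0, 49.0, 1010.0, 990.0, 1000.0, 5000.0, 4950.0, 5000.0],
        "firefly_3": [49.0, 50.0, 52.0, 1040.0, 980.0, 1020.0, 5100.0, 5000.0, 4950.0],
        "renilla_1": [10.0, 10.0, 11.0, 480.0, 520.0, 505.0, 490.0, 510.0, 500.0],
        "renilla_2": [10.0, 11.0, 10.0, 505.0, 495.0, 500.0, 505.0, 495.0, 498.0],
        "renilla_3": [11.0, 10.0, 10.0, 510.0, 490.0, 495.0, 500.0, 502.0, 501.0],
    }
)
luc = qn.luciferase_normalize(plate)
luc.to_csv(out_dir / "luciferase_normalized.csv", index=False)
anchor = luc.loc[luc["condition"] == "reporter_only", "normalized"].mean()
receptor = luc.loc[luc["condition"] == "receptor", "normalized"].mean()
print(f"luciferase: reporter-only mean {anchor:.3f} (anchored to 1), "
      f"receptor condition {receptor:.2f} a.u.")

# --- western-blot normalization ----------------------------------------
bands = pd.DataFrame(
    [
        {"exposure": "10s", "lane": "CD28_control", "mesa_intensity": 120.0,
         "nanoluc_intensity": 240.0},
        {"exposure": "10s", "lane": "GpA", "mesa_intensity": 300.0,
         "nanoluc_intensity": 250.0},
        {"exposure": "10s", "lane": "FGFR4", "mesa_intensity": 60.0,
         "nanoluc_intensity": 230.0},
        {"exposure": "60s", "lane": "CD28_control", "mesa_intensity": 700.0,
         "nanoluc_intensity": 1400.0},
        {"exposure": "60s", "lane": "GpA", "mesa_intensity": 1780.0,
         "nanoluc_intensity": 1450.0},
        {"exposure": "60s", "lane": "FGFR4", "mesa_intensity": 345.0,
         "nanoluc_intensity": 1350.0},
    ]
)
west = qn.western_normalize(bands, control_lane="CD28_control")
west.to_csv(out_dir / "western_relative_expression.csv", index=False)
print("western relative expression (vs CD28 control lane):")
print(west[["lane", "relative_expression", "suggested_dose_factor"]]
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
io.write_provenance(out_dir / "provenance.json", bead_slope=cal.slope,
                    bead_slope_se=cal.slope_se, seed=0)
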