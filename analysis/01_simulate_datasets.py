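"""Generate the synthetic study datasets and export them to disk.

Writes, under results/data/: one flow FRET sample with its five-member
control panel and ground truth (CSV), a rapalog dose titration, ten
microscopy fields for a sample plus single-color/vector-only control
fields (TIFF triplets), and calibration bead sets. Later analysis scripts
regenerate the same data in memory from the shared configurations, so
this script exists to give the datasets a file form, not to feed them.
"""

import dataclasses
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from shared import DATA_DIR, DOSES, REFS, base_config, image_config

from fretquant import io, synthdata as sd

flow_dir = DATA_DIR / "flow"
flow_dir.mkdir(parents=True, exist_ok=True)

cfg = base_config()
events, truth = sd.simulate_flow_sample(cfg, label="sample", treatment="ligand")
io.write_events_csv(events, flow_dir / "sample_100nM.csv")
truth.to_csv(flow_dir / "sample_100nM_truth.csv", index=False)
for name, table in sd.simulate_control_set(cfg).items():
    io.write_events_csv(table, flow_dir / f"{name}.csv")
print(f"flow: wrote sample ({len(events)} events) + 5 controls to {flow_dir}")

for dose in DOSES:
    ev, _ = sd.simulate_flow_sample(dataclasses.replace(cfg, ligand_dose=dose))
    io.write_events_csv(ev, flow_dir / f"titration_{dose:g}nM.csv")
print(f"flow: wrote {len(DOSES)}-point dose titration")

img_dir = DATA_DIR / "images"
icfg = image_config()
for name, c in {"sample": icfg, **sd.control_configs(icfg)}.items():
    if name in ("negative", "positive"):
        continue
    sub = img_dir / name
    sub.mkdir(parents=True, exist_ok=True)
    for i, (field, ftruth) in enumerate(sd.simulate_image_fields(c, 10, sample_id=name)):
        io.write_image_field(field, sub / f"field{i:02d}")
        ftruth.cells.to_csv(sub / f"field{i:02d}_truth.csv", index=False)
print(f"images: wrote 10 fields x 4 samples to {img_dir}")

beads_dir = DATA_DIR / "beads"
beads_dir.mkdir(parents=True, exist_ok=True)
for cv in (0.0, 0.05):
    table = sd.simulate_bead_set(REFS, true_slope=2.0, cv=cv, n_per_subpop=500, seed=0)
    io.write_events_csv(table, beads_dir / f"beads_cv{cv:g}.csv")
print(f"beads: wrote 2 bead sets ({len(REFS)} subpopulations x 500) to {beads_dir}")
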