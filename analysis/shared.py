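"""Shared study configuration for the analysis drivers.

One place defines the synthetic study conditions (sample size, noise,
bleed-through truth, dose grid, bead references) so every numbered script
analyzes the same simulated experiment.
"""

import dataclasses
import pathlib

from fretquant.synthdata import SimConfig, SpilloverTruth

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS_DIR = ROOT / "results"
DATA_DIR = RESULTS_DIR / "data"

#: true bleed-through fractions of the simulated instrument
TRUE_ABCD = {"a": 0.15, "b": 0.02, "c": 0.05, "d": 0.40}
#: rapalog dose grid (nM) for the titration
DOSES = (0.0, 1.0, 3.0, 10.0, 30.0, 100.0)
#: ectodomain C-terminal distances (Å) of the four simulated receptor systems
DISTANCES = (8.0, 22.0, 35.0, 50.0)
#: representative (synthetic) six-subpopulation bead reference values, MEFL
REFS = [693.0, 2192.0, 10885.0, 34169.0, 110674.0, 325845.0]


def base_config(seed: int = 0) -> SimConfig:
    """Flow study conditions: defaults of the generator."""
    return SimConfig(seed=seed, mixing=SpilloverTruth.from_bleedthrough(**TRUE_ABCD))


def image_config(seed: int = 0) -> SimConfig:
    """Imaging study conditions: bright cells over negligible background,
    so ratio-based bleed-through estimation is unbiased."""
    return dataclasses.replace(base_config(seed), autofl_mu=None)


def results_dir(name: str) -> pathlib.Path:
    out = RESULTS_DIR / name
    out.mkdir(parents=True, exist_ok=True)
    return out
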