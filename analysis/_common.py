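"""Shared paths and helpers for the numbered analysis drivers.

Heavy intermediates (simulated reads, per-subject peak BEDs, figures)
live under scratch/; the small summary tables each step reports go to
results/.
"""

from pathlib import Path

import yaml

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
SIM_DIR = SCRATCH / "sim"
RUN_DIR = SCRATCH / "run"
FIG_DIR = SCRATCH / "figures"
RESULTS = ROOT / "results"

STUDY_SEED = 1


def load_run_config():
    with open(SIM_DIR / "run.yaml", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def ensure_dirs():
    for d in (SCRATCH, SIM_DIR, RUN_DIR, FIG_DIR, RESULTS):
        d.mkdir(parents=True, exist_ok=True)
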