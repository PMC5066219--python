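"""Shared plumbing for the numbered analysis scripts.

The reference bundle is the default synthetic dataset at seed 1: a
2,000-gene preferential-attachment interactome, 8 tissues expressing 10%
of genes each (localization strength 0.9), 12 diseases of 25 genes with
4 planted disease-tissue modules, and GO/GWAS layers with coherence
planted inside the modules. `01_simulate.py` materializes it under
scratch/data/; the other scripts regenerate it deterministically when
those files are absent, so every script can run standalone.
"""

from __future__ import annotations

from pathlib import Path

from tissuemod.synthetic import SyntheticBundle, generate_bundle

REPO = Path(__file__).resolve().parent.parent
DATA_DIR = REPO / "scratch" / "data"
RESULTS_DIR = REPO / "results"

SEED = 1
N_REPS = 200


def reference_bundle() -> SyntheticBundle:
    return generate_bundle(seed=SEED)


def results_dir() -> Path:
    RESULTS_DIR.mkdir(parents=True, exist_ok=True)
    return RESULTS_DIR
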