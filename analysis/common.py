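"""Shared state for the numbered analysis scripts.

All scripts analyse the same seeded synthetic experiment (seed 42).  Raw
data (FASTQ, reference FASTA/GFF) live under scratch/analysis/; the small
result tables each script produces go to results/.  Every script can run
standalone: anything missing is regenerated deterministically.
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 42

sys.path.insert(0, str(ROOT / "src"))

from hypoxamir import preprocess, synthetic  # noqa: E402


def reference_and_simulation():
    ref = synthetic.build_toy_reference(SEED)
    profile = synthetic.default_profile(ref, seed=SEED)
    sim = synthetic.simulate_srna_libraries(ref, profile)
    return ref, profile, sim


def tag_libraries(ref=None, profile=None, sim=None):
    if sim is None:
        ref, profile, sim = reference_and_simulation()
    libs = {}
    stats = {}
    for cond in ("normoxic", "hypoxic"):
        libs[cond], stats[cond] = preprocess.preprocess_reads(
            sim.reads[cond], cond, cond, profile.adapter
        )
    return ref, profile, sim, libs, stats


def ensure_dirs():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
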