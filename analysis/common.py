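"""Shared setup for the analysis drivers: one synthetic dataset, cached under
scratch/, with the intron catalog and parsed fragments."""

from pathlib import Path

from flexiscan import annotations, detect, simulate

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "simdata"
RESULTS = ROOT / "results"

SEED = 7


def get_data():
    """Default-condition synthetic dataset (regenerated deterministically)."""
    return simulate.simulate_all(simulate.SimConfig(seed=SEED), outdir=SCRATCH)


def get_catalog(data):
    return annotations.build_intron_catalog(data.gtf_lines)


def get_fragments(data):
    return list(detect.fragments_from_alignments(data.paths["sam"]))


def ensure_results():
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
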