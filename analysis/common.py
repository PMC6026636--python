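"""Shared configuration for the analysis drivers.

One desk-scale synthetic study stands in for the sequencing cohort: the
full sample plan (9+13 two-week stools, 12+14 discharge stools, 11+10
skin swabs, 6+10 environmental swabs) at 10,000 reads per sample over 12
reference genomes of 50 kb. Bulk intermediates live under scratch/, small
result tables under results/.
"""

from pathlib import Path

from fingertax.pipeline import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "study_run"
RESULTS = ROOT / "results"

CONFIG = PipelineConfig(
    outdir=str(SCRATCH),
    seed=20260926 % (2 ** 31),
    simulation={"reads_per_sample": 10_000},
    min_fingerprint_frac=0.001,
)


def results_dir() -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    return RESULTS
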