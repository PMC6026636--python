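#!/usr/bin/env python
"""Build the fingerprint index and classify every sample.

Produces the samples x taxa count and relative-abundance matrices
(results/taxa_counts.tsv, results/taxa_abundance.tsv) that feed the
community statistics — the analogue of a study's genus-level heatmap
matrix.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, results_dir  # noqa: E402

from fingertax.pipeline import stage_classify, stage_index  # noqa: E402
from fingertax.synthetic_community import read_genomes_fasta  # noqa: E402


def main() -> None:
    outdir = Path(CONFIG.outdir)
    study = outdir / "study"
    genomes = read_genomes_fasta(study / "genomes.fasta")
    index = stage_index(CONFIG, genomes, study / "tree.nwk", outdir)
    strict = sum(1 for _, s in index.assignments.values() if s)
    print(f"index: {len(index)} canonical {index.k}-mers "
          f"({strict} strict, {len(index) - strict} relaxed)")
    meta = pd.read_csv(study / "metadata.tsv", sep="\t")
    counts = stage_classify(CONFIG, index, genomes, meta,
                            study / "reads", outdir)
    res = results_dir()
    for name in ("taxa_counts.tsv", "taxa_abundance.tsv"):
        shutil.copy(outdir / name, res / name)
    frac = counts.sum(axis=1) / 10_000
    print(f"classified {len(counts)} samples; median classified fraction "
          f"{frac.median():.3f} (min {frac.min():.3f})")


if __name__ == "__main__":
    main()
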