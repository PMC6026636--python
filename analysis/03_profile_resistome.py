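#!/usr/bin/env python
"""Profile the resistome/virulome of every sample.

Maps unassembled reads against the gene panel and writes the long-form
coverage table (results/gene_coverage.tsv): breadth of coverage, read
count and reads-per-million per gene and sample.
"""

import shutil
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, results_dir  # noqa: E402

from fingertax.gene_profiler import GenePanel  # noqa: E402
from fingertax.pipeline import stage_profile_genes  # noqa: E402


def main() -> None:
    outdir = Path(CONFIG.outdir)
    study = outdir / "study"
    panel = GenePanel.from_fasta(study / "panel.fasta")
    meta = pd.read_csv(study / "metadata.tsv", sep="\t")
    table = stage_profile_genes(CONFIG, panel, meta, study / "reads", outdir)
    shutil.copy(outdir / "gene_coverage.tsv", results_dir() / "gene_coverage.tsv")
    hit = table[table.read_count > 0]
    print(f"profiled {table.sample_id.nunique()} samples x {len(panel)} genes; "
          f"{len(hit)} positive sample-gene pairs")
    print(hit.groupby(['gene_id', 'cohort'])['rpm'].mean().round(1).to_string())


if __name__ == "__main__":
    main()
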