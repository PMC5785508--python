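#!/usr/bin/env python
"""Step 4 — characterize the simulated coding genes.

Runs the sequence-characterization pipeline (ORF → translation →
molecular weight → motif scan) on results/inputs/cdnas.fasta and checks
the planted values.  Writes results/seq_characterization.tsv.
"""

from pathlib import Path

from ifacecons.io_formats import read_json
from ifacecons.pipeline import PipelineConfig, run_seq_characterization

ROOT = Path(__file__).resolve().parent.parent / "results"
truth = read_json(ROOT / "inputs" / "cdna_truth.json")

config = PipelineConfig(cdna_fasta=str(ROOT / "inputs" / "cdnas.fasta"),
                        outdir=str(ROOT))
rows = run_seq_characterization(config)

for row in rows:
    expect = truth[row["record_id"]]
    ok = (row["orf_length_nt"] == expect["orf_nt"]
          and row["protein_length_aa"] == expect["protein_aa"])
    print(f"{row['record_id']}: ORF {row['orf_length_nt']} nt, "
          f"{row['protein_length_aa']} aa, "
          f"{row['molecular_weight_kda']:.1f} kDa, "
          f"motifs {row['motif_hits']} "
          f"({'matches' if ok else 'DOES NOT MATCH'} planted truth)")
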