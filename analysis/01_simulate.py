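#!/usr/bin/env python
"""Step 1 — generate the synthetic study inputs.

Writes under results/inputs/:
  complex.pdb           two-chain complex with a planted contact patch
  complex_truth.json    the planted patch (ground truth)
  reference.fasta       synthetic 1238-aa reference scaffold
  orthologs.fasta       one vertebrate-like and one starfish-like ortholog
  family_truth.json     regime labels and interface positions
  cdnas.fasta           caspase-scale and scaffold-scale coding genes
  cdna_truth.json       planted ORF lengths and motif anchors
"""

from pathlib import Path

from ifacecons.io_formats import write_fasta, write_json, write_pdb
from ifacecons.synthetic import (ComplexSpec, make_coding_gene, make_complex,
                                 make_family, regime_spec)

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20240101  # fixed so every downstream step is reproducible

# --- structure ------------------------------------------------------------
spec = ComplexSpec(n_res_target=30, n_res_partner=10,
                   patch_residues=(12, 13, 14, 15), seed=SEED)
structure, patch = make_complex(spec)
write_pdb(structure, OUT / "complex.pdb")
write_json({"target_chain": "A", "partner_chains": ["B"],
            "planted_patch": list(patch)}, OUT / "complex_truth.json")

# --- ortholog family -------------------------------------------------------
# same seed for both regimes: make_family draws the reference first, so
# equal seeds give both families the same reference sequence
vert = regime_spec("vertebrate", seed=SEED)
star = regime_spec("starfish", seed=SEED)
ref, (vert_orth,), _ = make_family(vert)
_, (star_orth,), _ = make_family(star)
vert_orth = type(vert_orth)(id="vertebrate_like", seq=vert_orth.seq,
                            moltype="protein", description=vert_orth.description)
star_orth = type(star_orth)(id="starfish_like", seq=star_orth.seq,
                            moltype="protein", description=star_orth.description)
write_fasta([ref], OUT / "reference.fasta")
write_fasta([vert_orth, star_orth], OUT / "orthologs.fasta")
write_json({
    "domain_span": list(vert.domain_span),
    "interface_positions": list(vert.interface_positions),
    "expected_reversal": {"vertebrate_like": False, "starfish_like": True},
}, OUT / "family_truth.json")

# --- coding genes -----------------------------------------------------------
casp_cdna, _ = make_coding_gene(452, SEED + 2, plant_motif="QACRG",
                                anchor_residue=305, anchor_offset=2,
                                gene_id="caspase_like")
apaf_cdna, _ = make_coding_gene(1238, SEED + 3, plant_motif="GSTGSGK",
                                anchor_residue=160, anchor_offset=0,
                                gene_id="apaf_like")
write_fasta([casp_cdna, apaf_cdna], OUT / "cdnas.fasta")
write_json({
    "caspase_like": {"orf_nt": 1356, "protein_aa": 452, "anchor_cys": 305},
    "apaf_like": {"orf_nt": 3714, "protein_aa": 1238, "walker_a_anchor": 160},
}, OUT / "cdna_truth.json")

print(f"wrote synthetic inputs to {OUT}")
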