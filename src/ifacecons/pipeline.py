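"""Config-driven orchestration of the two analysis pipelines.

Pipeline 1 (structure → interface → conservation):
    read_pdb → delta_sasa → call_interface → map interface residues
    (author numbering) onto the reference FASTA via a global alignment
    of the chain's extracted sequence → align orthologs → reversal report.

Pipeline 2 (sequence characterization):
    per cDNA record: ORF → translation → molecular weight → motif scan;
    plus local-alignment percent identity against any reference proteins.

Config files are flat ``key = value`` text; all paths are local (no
network fetching).  A provenance JSON with parameters, input checksums
and package version accompanies every run so results can be reproduced
bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .conservation import (DomainSpan, reversal_report, write_report_tsv)
from .interface import (DEFAULT_THRESHOLD, InterfaceSet, call_interface,
                        delta_sasa, sensitivity_report, write_interface_tsv,
                        DELTA_TABLE_COLUMNS)
from .io_formats import (SeqRecord, Structure, read_fasta, read_pdb,
                         write_json, write_tsv)
from .sasa import N_POINTS, PROBE_RADIUS, RadiusTable
from .seqtools import align_pair, find_orf, molecular_weight, percent_identity, scan_motif

logger = logging.getLogger(__name__)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U",
}

#: motifs reported by the sequence-characterization pipeline: pattern,
#: anchor index within the pattern (0-based).  QAC[RG]G anchors on the
#: catalytic Cys; the Walker-A motif GXXGXGK anchors on its first Gly.
DEFAULT_MOTIFS: tuple[tuple[str, int], ...] = (
    ("QAC[RG]G", 2),
    ("GXXGXGK", 0),
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of both pipelines, loadable from flat key=value text."""

    structure_pdb: str = ""
    target_chain: str = "A"
    partner_chains: tuple[str, ...] = ("B",)
    reference_fasta: str = ""
    ortholog_fasta: str = ""
    cdna_fasta: str = ""
    domain_start: int = 0
    domain_end: int = 0
    probe_radius: float = PROBE_RADIUS
    n_points: int = N_POINTS
    threshold: float = DEFAULT_THRESHOLD
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_chain_identity: float = 90.0
    radii_file: str = ""
    outdir: str = "results"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        values: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in cls.__dataclass_fields__:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                values[key] = raw
        cfg = cls()
        for key, raw in values.items():
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, raw.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(raw))
            elif isinstance(current, float):
                setattr(cfg, key, float(raw))
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(x.strip() for x in raw.split(",") if x.strip()))
            else:
                setattr(cfg, key, raw)
        return cfg

    def validate_structure_inputs(self) -> None:
        for label, p in (("structure_pdb", self.structure_pdb),
                         ("reference_fasta", self.reference_fasta),
                         ("ortholog_fasta", self.ortholog_fasta)):
            if not p or not Path(p).exists():
                raise PipelineError(f"config: {label} missing or not found: {p!r}")
        if not (1 <= self.domain_start <= self.domain_end):
            raise PipelineError("config: invalid domain span")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def chain_sequence(structure: Structure, chain: str) -> tuple[SeqRecord, list[tuple[str, int, str]]]:
    """One-letter sequence of a chain plus the residue key per position."""
    keys = []
    letters = []
    for key, res_name in structure.residues(chain):
        aa = THREE_TO_ONE.get(res_name)
        if aa is None:
            logger.warning("skipping non-standard residue %s at %s", res_name, key)
            continue
        keys.append(key)
        letters.append(aa)
    if not letters:
        raise PipelineError(f"chain {chain!r} has no standard residues")
    rec = SeqRecord(id=f"chain_{chain}", seq="".join(letters), moltype="protein")
    return rec, keys


def run_interface_conservation(config: PipelineConfig) -> dict:
    """Full structure→interface→conservation pipeline.

    Returns a dict with the delta table, interface set, sensitivity
    report, conservation report and provenance; also writes TSV/JSON
    outputs under config.outdir.
    """
    config.validate_structure_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        # --- structure and ΔSASA ------------------------------------------
        stage = "read_pdb"
        structure = read_pdb(config.structure_pdb)
        missing = ({config.target_chain} | set(config.partner_chains)) - set(structure.chains)
        if missing:
            raise PipelineError(f"{stage}: chain(s) {sorted(missing)} absent")

        stage = "delta_sasa"
        radii = RadiusTable.from_file(config.radii_file) if config.radii_file else None
        table = delta_sasa(structure, config.target_chain, config.partner_chains,
                           probe_radius=config.probe_radius,
                           n_points=config.n_points, radii=radii)

        stage = "call_interface"
        iface = call_interface(table, config.threshold,
                               target=config.target_chain,
                               partners=config.partner_chains)
        sensitivity = sensitivity_report(table)

        # --- map author numbering onto the reference FASTA ----------------
        stage = "map_to_reference"
        reference = read_fasta(config.reference_fasta, moltype="protein")[0]
        chain_rec, keys = chain_sequence(structure, config.target_chain)
        chain_aln = align_pair(chain_rec, reference, mode="global",
                               matrix=config.matrix, gap_open=config.gap_open,
                               gap_extend=config.gap_extend)
        # alignment_length denominator: robust even when a grossly wrong
        # reference aligns with no residue-residue columns at all
        chain_ident = percent_identity(chain_aln, "alignment_length")
        if chain_ident < config.min_chain_identity:
            raise PipelineError(
                f"{stage}: chain {config.target_chain!r} sequence is only "
                f"{chain_ident:.1f}% identical to the reference "
                f"(minimum {config.min_chain_identity}%) — chain mix-up?"
            )
        key_to_chain_pos = {k: i + 1 for i, k in enumerate(keys)}
        by_chain_pos = {q: s for q, s in chain_aln.column_map if q is not None}
        interface_ref_positions = []
        for row in iface.residues:
            key = (row["chain"], row["res_seq"], row["i_code"])
            cpos = key_to_chain_pos.get(key)
            if cpos is None:
                continue
            rpos = by_chain_pos.get(cpos)
            if rpos is not None:
                interface_ref_positions.append(rpos)
        if not interface_ref_positions:
            raise PipelineError(f"{stage}: no interface residue maps onto the reference")

        # --- conservation --------------------------------------------------
        stage = "reversal_report"
        orthologs = read_fasta(config.ortholog_fasta, moltype="protein")
        span = DomainSpan(seq_id=reference.id, start=config.domain_start,
                          end=config.domain_end)
        report = reversal_report(reference, orthologs, span,
                                 interface_ref_positions,
                                 matrix=config.matrix,
                                 gap_open=config.gap_open,
                                 gap_extend=config.gap_extend)

        # --- outputs --------------------------------------------------------
        stage = "write_outputs"
        p = outdir / "delta_sasa.tsv"
        write_tsv(table, DELTA_TABLE_COLUMNS, p); written.append(p)
        p = outdir / "interface.tsv"
        write_interface_tsv(iface, p); written.append(p)
        p = outdir / "conservation.tsv"
        write_report_tsv(report, p); written.append(p)
        provenance = {
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "inputs": {
                "structure_pdb": _sha256(config.structure_pdb),
                "reference_fasta": _sha256(config.reference_fasta),
                "ortholog_fasta": _sha256(config.ortholog_fasta),
            },
            "chain_to_reference_identity": round(chain_ident, 4),
            "interface_reference_positions": interface_ref_positions,
            "sensitivity": {f"{t:g}": n for t, n in sensitivity.items()},
        }
        p = outdir / "provenance.json"
        write_json(provenance, p); written.append(p)
    except PipelineError:
        for f in written:
            f.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for f in written:
            f.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {
        "delta_table": table,
        "interface": iface,
        "sensitivity": sensitivity,
        "report": report,
        "provenance": provenance,
    }


SEQCHAR_COLUMNS = (
    "record_id", "orf_start", "orf_length_nt", "protein_length_aa",
    "molecular_weight_kda", "motif_hits", "identities",
)


def run_seq_characterization(config: PipelineConfig,
                             motifs: tuple[tuple[str, int], ...] = DEFAULT_MOTIFS) -> list[dict]:
    """Characterize each cDNA record: ORF, length, MW, motifs, identities.

    Identities are best local-alignment percent identity (over aligned
    columns — the convention is recorded in the output) against every
    record of the reference FASTA, when one is provided.
    """
    if not config.cdna_fasta or not Path(config.cdna_fasta).exists():
        raise PipelineError(f"config: cdna_fasta missing or not found: {config.cdna_fasta!r}")
    cdnas = read_fasta(config.cdna_fasta, moltype="dna")
    references = []
    if config.reference_fasta:
        references = read_fasta(config.reference_fasta, moltype="protein")

    rows: list[dict] = []
    for rec in cdnas:
        orf = find_orf(rec)
        protein = orf.protein
        mw = molecular_weight(protein)
        hits = []
        for pattern, anchor in motifs:
            for h in scan_motif(protein, pattern, anchor_index=anchor):
                hits.append(f"{pattern}@{h.start}(anchor={h.anchor_pos})")
        idents = []
        for ref in references:
            aln = align_pair(protein, ref, mode="local", matrix=config.matrix,
                             gap_open=config.gap_open, gap_extend=config.gap_extend)
            ident = percent_identity(aln, "aligned_columns")
            idents.append(f"{ref.id}:{ident:.1f}%(local,aligned_columns)")
        rows.append({
            "record_id": rec.id,
            "orf_start": orf.start,
            "orf_length_nt": orf.length_nt,
            "protein_length_aa": len(protein),
            "molecular_weight_kda": round(mw, 4),
            "motif_hits": ";".join(hits) if hits else "-",
            "identities": ";".join(idents) if idents else "-",
        })
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(rows, SEQCHAR_COLUMNS, outdir / "seq_characterization.tsv")
    return rows
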