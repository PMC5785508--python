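"""Cross-species conservation of interface residues vs. a whole domain.

Given a reference protein, a set of interface positions on it (from the
ΔSASA analysis) and a domain span (e.g. the WD40 repeat region), each
ortholog is aligned pairwise to the reference and two identities are
computed:

* domain identity — fraction of reference positions inside the domain
  span whose aligned ortholog residue is identical;
* interface identity — the same fraction over the interface positions
  only.

A species shows the conservation *reversal* when its interface identity
falls below its domain identity: binding-site residues are normally the
better conserved part of a domain, so the reversal is evidence that the
ortholog does not maintain the binding site.

Reference positions that align to a gap in the ortholog (deletions) are
counted as mismatches by default, because a deleted interface loop is
exactly the kind of non-conservation the statistic must see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .io_formats import SeqRecord, write_tsv
from .seqtools import PairwiseAlignment, align_pair

DELETED = "DELETED"

REPORT_COLUMNS = (
    "species_id", "domain_identity", "interface_identity",
    "n_interface_positions", "n_interface_aligned", "n_interface_deleted",
    "reversal",
)


@dataclass(frozen=True)
class DomainSpan:
    """1-based inclusive residue span of a domain on a named sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}..{self.end}")

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ConservationReport:
    reference_id: str
    interface_positions: tuple[int, ...]
    per_species: list[dict]  # rows with REPORT_COLUMNS keys

    def rows(self) -> list[dict]:
        return self.per_species


def map_positions(aln: PairwiseAlignment,
                  ref_positions: Sequence[int]) -> dict[int, int | str]:
    """Map 1-based reference (query) positions through an alignment.

    Returns, per reference position, the 1-based subject position or the
    sentinel ``DELETED`` when the position aligns to a gap.  Positions
    outside the aligned query span raise.
    """
    by_query: dict[int, int | None] = {}
    for qpos, spos in aln.column_map:
        if qpos is not None:
            by_query[qpos] = spos
    out: dict[int, int | str] = {}
    for pos in ref_positions:
        if pos not in by_query:
            raise ValueError(
                f"reference position {pos} outside the aligned span of "
                f"{aln.query_id!r} vs {aln.subject_id!r}"
            )
        spos = by_query[pos]
        out[pos] = DELETED if spos is None else spos
    return out


def interface_identity(ref: SeqRecord, ortho: SeqRecord,
                       interface_positions: Sequence[int],
                       aln: PairwiseAlignment,
                       deleted_policy: str = "count_as_mismatch") -> float:
    """Percent identity over the interface positions of the reference.

    ``deleted_policy``: "count_as_mismatch" keeps deleted positions in
    the denominator (default — a deleted interface residue is not
    conserved); "exclude" drops them from both counts.
    """
    if deleted_policy not in ("count_as_mismatch", "exclude"):
        raise ValueError(f"unknown deleted policy {deleted_policy!r}")
    if not interface_positions:
        raise ValueError("empty interface position set")
    mapping = map_positions(aln, interface_positions)
    matches = 0
    denom = 0
    for pos in interface_positions:
        target = mapping[pos]
        if target == DELETED:
            if deleted_policy == "count_as_mismatch":
                denom += 1
            continue
        denom += 1
        if ortho.seq[target - 1] == ref.seq[pos - 1]:
            matches += 1
    if denom == 0:
        raise ValueError("no interface positions retained under 'exclude' policy")
    return 100.0 * matches / denom


def domain_identity(ref: SeqRecord, ortho: SeqRecord, span: DomainSpan,
                    aln: PairwiseAlignment) -> float:
    """Percent identity over all reference positions inside a domain span.

    Denominator = number of reference positions in the span; reference
    positions deleted in the ortholog count against identity.
    """
    if span.end > len(ref.seq):
        raise ValueError(f"span {span.start}..{span.end} outside reference "
                         f"of length {len(ref.seq)}")
    mapping = map_positions(aln, list(span.positions()))
    matches = 0
    for pos in span.positions():
        target = mapping[pos]
        if target == DELETED:
            continue
        if ortho.seq[target - 1] == ref.seq[pos - 1]:
            matches += 1
    return 100.0 * matches / len(span)


def reversal_report(ref: SeqRecord, orthologs: Sequence[SeqRecord],
                    span: DomainSpan, interface_positions: Sequence[int],
                    deleted_policy: str = "count_as_mismatch",
                    matrix: str = "BLOSUM62", gap_open: float = 10.0,
                    gap_extend: float = 0.5) -> ConservationReport:
    """Per-ortholog domain vs. interface identity with the reversal flag.

    Each ortholog is globally aligned to the reference; rows keep the
    input order.  ``reversal`` is true when interface identity is
    strictly below domain identity.
    """
    if not orthologs:
        raise ValueError("need at least one ortholog")
    ids = [o.id for o in orthologs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated species ids in ortholog set")
    bad = [p for p in interface_positions if not span.start <= p <= span.end]
    if bad:
        raise ValueError(f"interface positions {bad} outside domain span")

    rows: list[dict] = []
    for ortho in orthologs:
        aln = align_pair(ref, ortho, mode="global", matrix=matrix,
                         gap_open=gap_open, gap_extend=gap_extend)
        mapping = map_positions(aln, interface_positions)
        n_del = sum(1 for v in mapping.values() if v == DELETED)
        dom = domain_identity(ref, ortho, span, aln)
        ifc = interface_identity(ref, ortho, interface_positions, aln,
                                 deleted_policy=deleted_policy)
        rows.append({
            "species_id": ortho.id,
            "domain_identity": dom,
            "interface_identity": ifc,
            "n_interface_positions": len(interface_positions),
            "n_interface_aligned": len(interface_positions) - n_del,
            "n_interface_deleted": n_del,
            "reversal": ifc < dom,
        })
    return ConservationReport(
        reference_id=ref.id,
        interface_positions=tuple(interface_positions),
        per_species=rows,
    )


def write_report_tsv(report: ConservationReport, path) -> None:
    write_tsv(report.per_species, REPORT_COLUMNS, path)


def write_mapping_tsv(ref: SeqRecord, ortho: SeqRecord,
                      aln: PairwiseAlignment, positions: Sequence[int],
                      path) -> None:
    """Per-position mapping table (ref_pos, ref_aa, subject_pos, subject_aa, match)."""
    mapping = map_positions(aln, positions)
    rows = []
    for pos in positions:
        target = mapping[pos]
        if target == DELETED:
            rows.append({"ref_pos": pos, "ref_aa": ref.seq[pos - 1],
                         "subject_pos": "DEL", "subject_aa": "-", "match": False})
        else:
            aa = ortho.seq[target - 1]
            rows.append({"ref_pos": pos, "ref_aa": ref.seq[pos - 1],
                         "subject_pos": target, "subject_aa": aa,
                         "match": aa == ref.seq[pos - 1]})
    write_tsv(rows, ("ref_pos", "ref_aa", "subject_pos", "subject_aa", "match"), path)
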