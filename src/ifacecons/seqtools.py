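"""Sequence-level computations: ORF finding, translation, predicted
molecular weight, motif scanning, pairwise alignment and percent identity.

Alignment conventions
---------------------
Pairwise alignments use affine gap penalties with BLOSUM62 by default
(gap open 10, extend 0.5, i.e. a gap of length k costs 10 + (k-1)*0.5),
the convention of classic BLAST-style tools.  Percent identity defaults
to the *aligned columns* denominator: columns where both sequences carry
a residue.  Both choices are configurable because published identity
figures rarely state their convention.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .io_formats import SeqRecord

# ---------------------------------------------------------------------------
# ORF finding and translation

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """An ATG-initiated open reading frame on the forward strand.

    ``start`` is the 0-based offset of the A of the initiator ATG;
    ``length_nt`` excludes the stop codon, so length_nt == 3 * len(protein).
    """

    start: int
    length_nt: int
    protein: SeqRecord
    strand: int = 1


def translate(cds: SeqRecord, allow_internal_stop: bool = False) -> SeqRecord:
    """Translate a CDS with the standard genetic code (table 1).

    Codons containing N translate to X.  A trailing stop codon is
    stripped; an internal stop raises unless ``allow_internal_stop``.
    """
    if cds.moltype != "dna":
        raise ValueError("translate expects a dna record")
    if len(cds.seq) % 3 != 0:
        raise ValueError(f"CDS length {len(cds.seq)} not a multiple of 3")
    aa = str(Seq(cds.seq).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        idx = aa.index("*")
        if not allow_internal_stop:
            raise ValueError(f"internal stop codon at codon {idx + 1}")
        aa = aa.replace("*", "X")
    return SeqRecord(id=cds.id, seq=aa, moltype="protein",
                     description=f"translation of {cds.id}")


def find_orf(cdna: SeqRecord, policy: str = "longest_atg_to_stop",
             scan_both_strands: bool = False) -> OrfRecord:
    """Return the longest ATG-initiated reading frame ending at a stop.

    The stop codon is required but excluded from ``length_nt``.  Ties are
    broken by the smallest start offset (forward strand preferred when
    scanning both strands).
    """
    if policy != "longest_atg_to_stop":
        raise ValueError(f"unknown ORF policy {policy!r}")
    if cdna.moltype != "dna":
        raise ValueError("find_orf expects a dna record")
    if len(cdna.seq) < 6:
        raise ValueError("sequence too short to contain an ORF")

    def scan(seq: str) -> tuple[int, int] | None:
        best: tuple[int, int] | None = None  # (length_nt, start), maximised
        for frame in range(3):
            start: int | None = None
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        length = i - start
                        if best is None or length > best[0] or (
                            length == best[0] and start < best[1]
                        ):
                            best = (length, start)
                        start = None
                elif codon == "ATG" and start is None:
                    start = i
        return best

    candidates: list[tuple[int, int, int]] = []  # (length, start, strand)
    fwd = scan(cdna.seq)
    if fwd:
        candidates.append((fwd[0], fwd[1], 1))
    if scan_both_strands:
        rc = str(Seq(cdna.seq).reverse_complement())
        rev = scan(rc)
        if rev:
            candidates.append((rev[0], rev[1], -1))
    if not candidates:
        raise ValueError(f"no ATG..stop open reading frame in {cdna.id!r}")
    length, start, strand = max(candidates, key=lambda c: (c[0], -c[1], c[2]))
    seq = cdna.seq if strand == 1 else str(Seq(cdna.seq).reverse_complement())
    cds = SeqRecord(id=cdna.id, seq=seq[start : start + length], moltype="dna")
    protein = translate(cds)
    return OrfRecord(start=start, length_nt=length, protein=protein, strand=strand)


# ---------------------------------------------------------------------------
# molecular weight

#: Average residue masses (Da) of the 20 amino acids as they occur in a
#: peptide chain (monomer mass minus one water).  One water (18.0153 Da)
#: is added back per chain.
RESIDUE_MASS_DA: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.0153


def molecular_weight(protein: SeqRecord) -> float:
    """Predicted average molecular weight of a protein chain, in kDa."""
    if protein.moltype != "protein":
        raise ValueError("molecular_weight expects a protein record")
    try:
        total = sum(RESIDUE_MASS_DA[aa] for aa in protein.seq)
    except KeyError as exc:
        raise ValueError(f"no mass for residue {exc.args[0]!r}") from None
    return (total + WATER_MASS_DA) / 1000.0


# ---------------------------------------------------------------------------
# motif scanning

@dataclass(frozen=True)
class MotifHit:
    pattern_id: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    matched: str
    anchor_pos: int  # 1-based position of the pattern's anchor residue


def _compile_motif(pattern: str) -> tuple[re.Pattern, int]:
    """Compile the motif mini-grammar to a regex.

    Grammar: literal residues, ``X`` wildcard, ``[AB]`` alternatives.
    Returns the compiled regex and the number of positions in the motif.
    """
    out = []
    n_pos = 0
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise ValueError(f"unclosed '[' in motif {pattern!r}")
            alts = pattern[i + 1 : j]
            if not alts or not alts.isalpha():
                raise ValueError(f"bad alternative set in motif {pattern!r}")
            out.append(f"[{alts.upper()}]")
            n_pos += 1
            i = j + 1
        elif ch.upper() == "X":
            out.append("[A-Z]")
            n_pos += 1
            i += 1
        elif ch.isalpha():
            out.append(ch.upper())
            n_pos += 1
            i += 1
        else:
            raise ValueError(f"illegal character {ch!r} in motif {pattern!r}")
    if n_pos == 0:
        raise ValueError("empty motif pattern")
    return re.compile("".join(out)), n_pos


def scan_motif(protein: SeqRecord, pattern: str, anchor_index: int = 0,
               pattern_id: str | None = None) -> list[MotifHit]:
    """All non-overlapping leftmost matches of a motif pattern.

    ``anchor_index`` is the 0-based position within the pattern of the
    anchor residue (e.g. 2 for the catalytic Cys of QAC[RG]G).
    """
    regex, n_pos = _compile_motif(pattern)
    if not 0 <= anchor_index < n_pos:
        raise ValueError(f"anchor index {anchor_index} outside motif of {n_pos} positions")
    hits = []
    for m in regex.finditer(protein.seq):
        start = m.start() + 1
        hits.append(MotifHit(
            pattern_id=pattern_id or pattern, start=start,
            end=m.end(), matched=m.group(0),
            anchor_pos=start + anchor_index,
        ))
    return hits


# ---------------------------------------------------------------------------
# pairwise alignment

@dataclass
class PairwiseAlignment:
    """An aligned pair of protein sequences with its column map.

    ``column_map`` holds, per alignment column, a pair
    (query residue position or None, subject residue position or None),
    positions 1-based in the *full* input sequences (relevant for local
    mode, where the alignment may cover only a subsequence).
    """

    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    score: float
    mode: str
    column_map: list[tuple[int | None, int | None]] = field(repr=False, default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    def identical_columns(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_query, self.aligned_subject)
            if a == b and a != "-"
        )

    def aligned_columns(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_query, self.aligned_subject)
            if a != "-" and b != "-"
        )


@lru_cache(maxsize=8)
def load_matrix(name: str):
    return substitution_matrices.load(name)


def _make_aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = load_matrix(matrix)
    # affine convention: a gap of length k costs open + (k-1) * extend
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(a: SeqRecord, b: SeqRecord, mode: str = "global",
               matrix: str = "BLOSUM62", gap_open: float = 10.0,
               gap_extend: float = 0.5) -> PairwiseAlignment:
    """Optimal affine-gap pairwise alignment (Needleman-Wunsch /
    Smith-Waterman via dynamic programming).

    Returns the single best-scoring alignment; among co-optimal
    alignments the traceback choice is deterministic.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if not a.seq or not b.seq:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(mode, matrix, gap_open, gap_extend)
    alignments = aligner.align(a.seq, b.seq)
    if mode == "local" and len(alignments) == 0:
        # no positive-scoring local alignment exists: the optimum is empty
        return PairwiseAlignment(
            query_id=a.id, subject_id=b.id, aligned_query="",
            aligned_subject="", score=0.0, mode=mode, column_map=[],
        )
    aln = alignments[0]
    qa, sa = str(aln[0]), str(aln[1])
    # in local mode the aligned strings cover only the aligned segment, so
    # positions are offset by the unaligned prefix; global strings cover all
    if mode == "local":
        q_off = int(aln.aligned[0][0][0]) if len(aln.aligned[0]) else 0
        s_off = int(aln.aligned[1][0][0]) if len(aln.aligned[1]) else 0
    else:
        q_off = s_off = 0
    column_map: list[tuple[int | None, int | None]] = []
    qi, si = q_off, s_off
    for cq, cs in zip(qa, sa):
        qpos = None
        spos = None
        if cq != "-":
            qi += 1
            qpos = qi
        if cs != "-":
            si += 1
            spos = si
        column_map.append((qpos, spos))
    return PairwiseAlignment(
        query_id=a.id, subject_id=b.id, aligned_query=qa, aligned_subject=sa,
        score=float(aln.score), mode=mode, column_map=column_map,
    )


def percent_identity(aln: PairwiseAlignment,
                     denominator: str = "aligned_columns") -> float:
    """Percent identity of an alignment under a named denominator.

    ``aligned_columns``: columns where both sequences have a residue;
    ``alignment_length``: all columns including gaps;
    ``shorter_seq``: length of the shorter of the two aligned segments.
    Gap columns never count as identical.
    """
    ident = aln.identical_columns()
    if denominator == "aligned_columns":
        denom = aln.aligned_columns()
    elif denominator == "alignment_length":
        denom = aln.n_columns
    elif denominator == "shorter_seq":
        denom = min(
            sum(1 for c in aln.aligned_query if c != "-"),
            sum(1 for c in aln.aligned_subject if c != "-"),
        )
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("empty alignment")
    return 100.0 * ident / denom


# ---------------------------------------------------------------------------
# brute-force alignment oracle (independent of the DP implementation)

def brute_force_score(a: str, b: str, mode: str = "global",
                      matrix: str = "BLOSUM62", gap_open: float = 10.0,
                      gap_extend: float = 0.5) -> float:
    """Optimal affine-gap alignment score by exhaustive path enumeration.

    Enumerates every monotone alignment path (match / insert / delete
    moves) and scores it with the affine convention
    cost(gap of length k) = open + (k-1) * extend.  Exponential: intended
    for tiny sequences only, as an independent check of align_pair.
    """
    m = load_matrix(matrix)

    def sub(x: str, y: str) -> float:
        return float(m[x, y])

    if mode == "global":
        return _brute_global(a, b, sub, gap_open, gap_extend)
    if mode == "local":
        # best global score over all substring pairs; empty alignment scores 0
        out = 0.0
        for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
            for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
                out = max(out, _brute_global(a[i0:i1], b[j0:j1], sub, gap_open, gap_extend))
        return out
    raise ValueError(f"unknown mode {mode!r}")


def _brute_global(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    best = -float("inf")
    stack = [(0, 0, 0.0, "")]
    while stack:
        i, j, score, prev = stack.pop()
        if i == len(a) and j == len(b):
            if score > best:
                best = score
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, score + sub(a[i], b[j]), "M"))
        if i < len(a):
            stack.append((i + 1, j, score - (gap_extend if prev == "D" else gap_open), "D"))
        if j < len(b):
            stack.append((i, j + 1, score - (gap_extend if prev == "I" else gap_open), "I"))
    return best
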