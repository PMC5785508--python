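"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators:

* :func:`make_complex` — a toy two-chain complex in which a chosen set
  of target residues ("the patch") is buried by partner atoms and every
  other residue is geometrically guaranteed zero ΔSASA.  Stands in for
  a real receptor/ligand complex when testing interface detection.

* :func:`make_family` — an ortholog family in which interface and
  background positions diverge at independently controlled substitution
  rates, optionally with long deletion blocks spanning interface loops.
  The two built-in regimes emulate the biology the pipeline is meant to
  distinguish: a "vertebrate-like" regime where the binding site is the
  best-conserved part of the domain, and a "starfish-like" regime where
  the binding site decays faster than the domain and interface loops
  are deleted outright.

Geometry of make_complex: the target chain is a straight Cα trace with
3.8 Å spacing and carbon radii (1.70 Å).  With a 1.4 Å probe, two atoms
interact iff they are closer than r_i + r_j + 2p = 6.2 Å.  One partner
atom is placed 5.2 Å above each patch residue: 5.2 < 6.2 buries the
patch residue, while the nearest non-patch residue lies at
sqrt(5.2² + 3.8²) = 6.44 Å > 6.2 and is untouched.  Remaining partner
residues are parked ``separation`` Å away (default 25 Å).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import DomainSpan
from .io_formats import AtomRecord, SeqRecord, Structure

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CA_SPACING = 3.8     # Å between consecutive Cα atoms
CONTACT_OFFSET = 5.2  # Å partner height above a patch residue
BURIAL_REACH = 6.2   # Å: 2 * (1.70 + 1.4) for carbon atoms, water probe


@dataclass(frozen=True)
class ComplexSpec:
    """Recipe for a two-chain toy complex with a planted contact patch."""

    n_res_target: int = 20
    n_res_partner: int = 8
    patch_residues: tuple[int, ...] = (5, 6, 7)  # 1-based target residues
    separation: float = 25.0  # Å, distance of non-contact partner residues
    seed: int = 0

    def __post_init__(self):
        bad = [p for p in self.patch_residues
               if not 1 <= p <= self.n_res_target]
        if bad:
            raise ValueError(f"patch residues {bad} outside 1..{self.n_res_target}")
        if len(self.patch_residues) > self.n_res_partner:
            raise ValueError("partner chain too short to cover the patch")
        if self.separation <= BURIAL_REACH:
            raise ValueError(
                f"separation {self.separation} must exceed the burial reach "
                f"{BURIAL_REACH} Å"
            )


def make_complex(spec: ComplexSpec) -> tuple[Structure, tuple[int, ...]]:
    """Build the toy complex; returns (structure, planted patch residues).

    Chain A is the target, chain B the partner.  Output is fully
    deterministic in the ComplexSpec fields (the seed adds no jitter
    here; it is kept for symmetry with make_family and future use).
    """
    atoms: list[AtomRecord] = []
    serial = 1
    for i in range(1, spec.n_res_target + 1):
        atoms.append(AtomRecord(
            serial=serial, atom_name="CA", alt_loc="", res_name="ALA",
            chain_id="A", res_seq=i, i_code="",
            x=(i - 1) * CA_SPACING, y=0.0, z=0.0, element="C",
        ))
        serial += 1
    res_b = 1
    for p in spec.patch_residues:
        atoms.append(AtomRecord(
            serial=serial, atom_name="CA", alt_loc="", res_name="ALA",
            chain_id="B", res_seq=res_b, i_code="",
            x=(p - 1) * CA_SPACING, y=CONTACT_OFFSET, z=0.0, element="C",
        ))
        serial += 1
        res_b += 1
    # park the remaining partner residues far from everything
    n_far = spec.n_res_partner - len(spec.patch_residues)
    for k in range(n_far):
        atoms.append(AtomRecord(
            serial=serial, atom_name="CA", alt_loc="", res_name="ALA",
            chain_id="B", res_seq=res_b, i_code="",
            x=k * CA_SPACING, y=spec.separation, z=spec.separation,
            element="C",
        ))
        serial += 1
        res_b += 1
    structure = Structure(atoms=atoms, source_id=f"synthetic-complex-{spec.seed}")
    return structure, tuple(spec.patch_residues)


# ---------------------------------------------------------------------------
# ortholog families

@dataclass(frozen=True)
class FamilySpec:
    """Recipe for an ortholog family with two-rate divergence.

    Defaults emulate the real study's scale: a 1238-residue scaffold
    whose domain of interest spans positions 621-1156, with 24 interface
    positions inside it.
    """

    ref_length: int = 1238
    domain_span: tuple[int, int] = (621, 1156)
    interface_positions: tuple[int, ...] = tuple(range(700, 712)) + tuple(range(950, 962))
    rate_interface: float = 0.05
    rate_background: float = 0.4
    deletion_blocks: tuple[tuple[int, int], ...] = ()  # (start, length) on reference
    n_species: int = 1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.domain_span
        if not 1 <= lo <= hi <= self.ref_length:
            raise ValueError(f"domain span {lo}..{hi} outside 1..{self.ref_length}")
        bad = [p for p in self.interface_positions if not lo <= p <= hi]
        if bad:
            raise ValueError(f"interface positions {bad} outside domain span")
        for rate in (self.rate_interface, self.rate_background):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"substitution rate {rate} outside [0, 1]")
        for start, length in self.deletion_blocks:
            if length < 1 or not lo <= start <= start + length - 1 <= hi:
                raise ValueError(
                    f"deletion block ({start}, {length}) outside domain span"
                )

    @property
    def span(self) -> DomainSpan:
        return DomainSpan(seq_id="ref", start=self.domain_span[0],
                          end=self.domain_span[1])


#: regime presets: the conditions the conservation statistic must separate
VERTEBRATE_LIKE = dict(rate_interface=0.05, rate_background=0.4,
                       deletion_blocks=())
STARFISH_LIKE = dict(rate_interface=0.5, rate_background=0.2,
                     deletion_blocks=((698, 10), (948, 10)))


def make_family(spec: FamilySpec) -> tuple[SeqRecord, list[SeqRecord], list[str]]:
    """Draw a reference and n_species orthologs under a FamilySpec regime.

    The reference is uniform over the 20 amino acids.  Each ortholog
    substitutes every position independently — at ``rate_interface`` on
    interface positions, ``rate_background`` everywhere else — drawing
    replacements uniformly from the 19 alternatives, then removes the
    deletion blocks.  Returns (reference, orthologs, truth labels); the
    label is "deleted" when deletion blocks apply, else "substituted-only".
    Fully deterministic in the seed.
    """
    rng = np.random.default_rng(spec.seed)
    ref_seq = "".join(rng.choice(list(AMINO_ACIDS), size=spec.ref_length))
    ref = SeqRecord(id="ref", seq=ref_seq, moltype="protein",
                    description="synthetic reference")

    iface = set(spec.interface_positions)
    deleted_positions = set()
    for start, length in spec.deletion_blocks:
        deleted_positions.update(range(start, start + length))

    orthologs: list[SeqRecord] = []
    labels: list[str] = []
    for s in range(spec.n_species):
        chars = []
        for pos in range(1, spec.ref_length + 1):
            if pos in deleted_positions:
                continue
            rate = spec.rate_interface if pos in iface else spec.rate_background
            aa = ref_seq[pos - 1]
            if rng.random() < rate:
                alternatives = AMINO_ACIDS.replace(aa, "")
                aa = alternatives[rng.integers(len(alternatives))]
            chars.append(aa)
        orthologs.append(SeqRecord(
            id=f"sp{s + 1}", seq="".join(chars), moltype="protein",
            description="synthetic ortholog",
        ))
        labels.append("deleted" if deleted_positions else "substituted-only")
    return ref, orthologs, labels


# ---------------------------------------------------------------------------
# coding-gene and divergent-pair stand-ins

#: one fixed codon per amino acid (deterministic back-translation)
CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def make_coding_gene(n_aa: int, seed: int,
                     plant_motif: str | None = None,
                     anchor_residue: int | None = None,
                     anchor_offset: int = 0,
                     utr5: int = 60, utr3: int = 90,
                     gene_id: str = "synthetic-gene") -> tuple[SeqRecord, SeqRecord]:
    """A synthetic cDNA with a planted ORF of exactly ``3 * n_aa`` nt.

    The protein starts with M; a literal motif instance can be planted so
    that its anchor residue (``anchor_offset`` 0-based within the motif)
    sits at protein position ``anchor_residue``.  UTRs are drawn from
    {C, T} only, so they can contain neither start nor stop codons, which
    makes the planted ORF the unique longest one.  Returns
    (cDNA record, protein record); fully deterministic in the seed.
    """
    rng = np.random.default_rng(seed)
    protein = ["M"] + [AMINO_ACIDS[rng.integers(20)] for _ in range(n_aa - 1)]
    if plant_motif is not None:
        if anchor_residue is None:
            raise ValueError("anchor_residue required when planting a motif")
        start = anchor_residue - 1 - anchor_offset  # 0-based motif start
        if start < 1 or start + len(plant_motif) > n_aa:
            raise ValueError("motif does not fit at the requested anchor")
        for i, aa in enumerate(plant_motif):
            protein[start + i] = aa
    protein_seq = "".join(protein)
    cds = "".join(CODON_OF[aa] for aa in protein_seq)
    u5 = "".join("CT"[rng.integers(2)] for _ in range(utr5))
    u3 = "".join("CT"[rng.integers(2)] for _ in range(utr3))
    cdna = SeqRecord(id=gene_id, seq=u5 + cds + "TAA" + u3, moltype="dna",
                     description="synthetic coding gene")
    prot = SeqRecord(id=gene_id, seq=protein_seq, moltype="protein",
                     description="synthetic protein")
    return cdna, prot


def mutate_protein(record: SeqRecord, n_substitutions: int, seed: int,
                   new_id: str = "mutant") -> SeqRecord:
    """Copy of a protein with exactly n distinct positions substituted.

    Gap-free by construction, so the expected global identity over
    aligned columns is exactly (L - n) / L.
    """
    if not 0 <= n_substitutions <= len(record.seq):
        raise ValueError("n_substitutions outside [0, length]")
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(record.seq), size=n_substitutions, replace=False)
    chars = list(record.seq)
    for p in positions:
        alternatives = AMINO_ACIDS.replace(chars[p], "")
        chars[p] = alternatives[rng.integers(len(alternatives))]
    return SeqRecord(id=new_id, seq="".join(chars), moltype="protein",
                     description=f"{record.id} with {n_substitutions} substitutions")


def regime_spec(regime: str, seed: int, n_species: int = 1, **overrides) -> FamilySpec:
    """FamilySpec for a named regime ("vertebrate" or "starfish")."""
    presets = {"vertebrate": VERTEBRATE_LIKE, "starfish": STARFISH_LIKE}
    if regime not in presets:
        raise ValueError(f"unknown regime {regime!r}")
    kwargs = dict(presets[regime])
    kwargs.update(overrides)
    return FamilySpec(seed=seed, n_species=n_species, **kwargs)
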