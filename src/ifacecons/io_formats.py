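"""Readers and writers for the formats the pipeline touches.

FASTA and PDB-format coordinate files come in; TSV and JSON reports go
out.  Conventions are deliberately explicit because downstream stages
depend on them:

* sequence ids must be unique within a file and residues are case-folded
  to upper case;
* PDB ATOM/HETATM records are parsed by fixed columns, residue numbers
  are kept verbatim from the file (author numbering, insertion codes
  included) and all reports cite residues in that numbering;
* floats in reports are serialized with 4 decimals.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")  # X = unknown residue
# extended protein letters allowed only when explicitly requested
PROTEIN_ALPHABET_EXTENDED = PROTEIN_ALPHABET | set("BXZUO*")
DNA_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates the documented conventions."""


@dataclass(frozen=True)
class SeqRecord:
    """A single sequence with an accession-like id.

    moltype is either ``"protein"`` or ``"dna"``; the sequence is stored
    upper-case and validated against the corresponding alphabet.
    """

    id: str
    seq: str
    moltype: str = "protein"
    description: str = ""

    def __post_init__(self):
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.moltype not in ("protein", "dna"):
            raise FormatError(f"record {self.id!r}: unknown moltype {self.moltype!r}")
        alphabet = PROTEIN_ALPHABET if self.moltype == "protein" else DNA_ALPHABET
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in alphabet:
                raise FormatError(
                    f"record {self.id!r}: illegal {self.moltype} residue "
                    f"{ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    atom_name: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    x: float
    y: float
    z: float
    element: str
    occupancy: float = 1.0
    is_het: bool = False

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """Identity of the residue this atom belongs to (author numbering)."""
        return (self.chain_id, self.res_seq, self.i_code)


@dataclass
class Structure:
    """An ordered list of atoms grouped into chains.

    Residue order within a chain follows file order; numbering is taken
    verbatim from the source file.
    """

    atoms: list[AtomRecord]
    source_id: str = ""

    @property
    def chains(self) -> dict[str, list[AtomRecord]]:
        out: dict[str, list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.chain_id, []).append(a)
        return out

    def chain_atoms(self, chain_ids: Iterable[str]) -> list[AtomRecord]:
        wanted = set(chain_ids)
        missing = wanted - set(self.chains)
        if missing:
            raise KeyError(f"chain(s) {sorted(missing)} absent from structure")
        return [a for a in self.atoms if a.chain_id in wanted]

    def residues(self, chain_id: str) -> list[tuple[tuple[str, int, str], str]]:
        """(residue_key, res_name) per residue of a chain, in file order."""
        seen: list[tuple[tuple[str, int, str], str]] = []
        keys: set[tuple[str, int, str]] = set()
        for a in self.chain_atoms([chain_id]):
            if a.residue_key not in keys:
                keys.add(a.residue_key)
                seen.append((a.residue_key, a.res_name))
        return seen


def read_fasta(path: str | Path, moltype: str = "protein") -> list[SeqRecord]:
    """Parse a (possibly wrapped) multi-record FASTA file.

    Whitespace and digits are stripped from sequence lines and residues
    are case-folded to upper before alphabet validation.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    ids: set[str] = set()
    parsed = list(SeqIO.parse(str(path), "fasta"))
    if not parsed:
        raise FormatError(f"{path}: no FASTA records found")
    for rec in parsed:
        if rec.id in ids:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        ids.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        seq = "".join(ch for ch in seq if not ch.isdigit())
        records.append(
            SeqRecord(id=rec.id, seq=seq, moltype=moltype, description=rec.description)
        )
    return records


def write_fasta(records: Sequence[SeqRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PDB fixed-column parsing

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


def _infer_element(atom_name: str, res_name: str) -> str:
    """Fallback element inference from the atom name columns."""
    name = atom_name.strip()
    if not name:
        return ""
    # two-letter elements in common het groups start in column 13; for
    # polymer atoms the first alpha character is the element
    if name[:2] in ("FE", "ZN", "MG", "MN", "CU", "NA", "CL", "CA") and res_name not in (
        "CA",
    ):
        # "CA" atom name in an amino acid is an alpha carbon, not calcium
        if not (name == "CA" and res_name not in _WATER_RESNAMES and len(res_name) == 3):
            return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def read_pdb(
    path: str | Path,
    model: int = 1,
    altloc_policy: str = "first",
    keep_het: bool = False,
    drop_waters: bool = True,
) -> Structure:
    """Parse ATOM/HETATM records of one model from a PDB-format file.

    Fixed-column parsing only.  HETATM records are excluded unless
    ``keep_het`` is set; waters are always dropped when ``drop_waters``
    is true.  The element is taken from columns 77-78 when present, else
    inferred from the atom name.  Duplicate alternate locations of the
    same atom are resolved by ``altloc_policy`` ("first" or
    "highest_occupancy").
    """
    if altloc_policy not in ("first", "highest_occupancy"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    path = Path(path)
    atoms: list[AtomRecord] = []
    # key without altloc -> index into atoms, for altloc resolution
    seen: dict[tuple, int] = {}
    current_model = 1
    model_seen = False
    models_found: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                try:
                    current_model = int(line[6:].split()[0])
                except (ValueError, IndexError):
                    raise FormatError(f"{path}:{lineno}: malformed MODEL record")
                model_seen = True
                models_found.add(current_model)
                continue
            if rec == "ENDMDL":
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            if not model_seen:
                models_found.add(1)
            if current_model != model:
                continue
            is_het = rec == "HETATM"
            res_name = line[17:20].strip()
            if is_het and drop_waters and res_name in _WATER_RESNAMES:
                continue
            if is_het and not keep_het:
                continue
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed numeric columns")
            if not all(math.isfinite(v) for v in (x, y, z)):
                raise FormatError(f"{path}:{lineno}: non-finite coordinate")
            try:
                occupancy = float(line[54:60])
            except ValueError:
                occupancy = 1.0
            atom_name = line[12:16].strip()
            alt_loc = line[16].strip()
            chain_id = line[21].strip() or " "
            try:
                res_seq = int(line[22:26])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed residue number")
            i_code = line[26].strip()
            element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(atom_name, res_name)
            atom = AtomRecord(
                serial=serial, atom_name=atom_name, alt_loc=alt_loc,
                res_name=res_name, chain_id=chain_id, res_seq=res_seq,
                i_code=i_code, x=x, y=y, z=z, element=element,
                occupancy=occupancy, is_het=is_het,
            )
            key = (chain_id, res_seq, i_code, atom_name)
            if alt_loc and key in seen:
                if altloc_policy == "highest_occupancy":
                    if occupancy > atoms[seen[key]].occupancy:
                        atoms[seen[key]] = atom
                # "first": keep the one already stored
                continue
            seen[key] = len(atoms)
            atoms.append(atom)
    if model_seen and model not in models_found:
        raise FormatError(f"{path}: model {model} not present (found {sorted(models_found)})")
    if not atoms:
        raise FormatError(f"{path}: no atoms parsed for model {model}")
    return Structure(atoms=atoms, source_id=path.stem)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column ATOM records (deterministic bytes)."""
    path = Path(path)
    with open(path, "w") as fh:
        for a in structure.atoms:
            rec = "HETATM" if a.is_het else "ATOM  "
            name = a.atom_name
            # PDB convention: atom names of <4 chars start in column 14
            name_field = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
            fh.write(
                f"{rec}{a.serial:>5d} {name_field}{a.alt_loc or ' '}"
                f"{a.res_name:>3s} {a.chain_id}{a.res_seq:>4d}{a.i_code or ' '}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# report serialization

FLOAT_FMT = "{:.4f}"


def _fmt(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return FLOAT_FMT.format(value)
    return str(value)


def write_tsv(rows: Sequence[dict], columns: Sequence[str], path: str | Path) -> None:
    """Write rows as TSV with a fixed, documented column order.

    Floats are formatted with 4 decimals; an empty row list yields a
    header-only file.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in columns) + "\n")


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
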