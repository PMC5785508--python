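"""Interface-residue detection by the Δaccessibility criterion.

A residue of the target chain belongs to the interface with a partner
chain if its solvent-accessible area drops when the partner is present:

    ΔSASA(residue) = SASA(chain alone) − SASA(chain in complex) > threshold

Both states are computed with identical quadrature, so the difference
is exactly the occlusion contributed by partner atoms.  The default
threshold is 1.0 Å² of residue-level ΔSASA: a strictly-positive cutoff
is meaningless under numerical quadrature, so a small positive value is
used and a sensitivity report across 0.1 / 1.0 / 5.0 Å² accompanies
every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import Structure, write_tsv
from .sasa import RadiusTable, compute_sasa, PROBE_RADIUS, N_POINTS

DEFAULT_THRESHOLD = 1.0  # Å² residue-level ΔSASA
SENSITIVITY_THRESHOLDS = (0.1, 1.0, 5.0)

#: numerical tolerance for "delta must be non-negative": differences more
#: negative than this indicate inconsistent unbound/bound contexts
NEGATIVE_DELTA_TOL = 1e-9

DELTA_TABLE_COLUMNS = (
    "chain", "res_seq", "i_code", "res_name",
    "sasa_unbound", "sasa_bound", "delta",
)


@dataclass
class InterfaceSet:
    """Residues of a target chain losing SASA upon complexation."""

    target_chain: str
    partner_chains: tuple[str, ...]
    residues: list[dict]  # rows with DELTA_TABLE_COLUMNS keys
    threshold: float

    def residue_numbers(self) -> list[int]:
        return [r["res_seq"] for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)


def delta_sasa(
    structure: Structure,
    target: str,
    partners: Sequence[str],
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    radii: RadiusTable | None = None,
) -> list[dict]:
    """Per-residue (unbound, bound, delta) table for a target chain.

    unbound: SASA of the target chain with only its own atoms occluding;
    bound: same selection with target + partner atoms occluding.
    """
    partners = tuple(partners)
    if target in partners:
        raise ValueError(f"target chain {target!r} also listed as partner")
    present = set(structure.chains)
    missing = ({target} | set(partners)) - present
    if missing:
        raise KeyError(f"chain(s) {sorted(missing)} absent from structure")

    # the bound context is target + partners only: other chains of the
    # structure must not contribute occlusion to either state
    complex_atoms = structure.chain_atoms((target,) + partners)
    sub = Structure(atoms=complex_atoms, source_id=structure.source_id)

    unbound = compute_sasa(sub, selection=(target,), probe_radius=probe_radius,
                           n_points=n_points, radii=radii, context="selection_only")
    bound = compute_sasa(sub, selection=(target,), probe_radius=probe_radius,
                         n_points=n_points, radii=radii, context="whole_structure")

    rows: list[dict] = []
    for key, res_name in sub.residues(target):
        u = unbound.per_residue[key]
        b = bound.per_residue[key]
        d = u - b
        if d < -NEGATIVE_DELTA_TOL:
            raise ValueError(
                f"negative ΔSASA {d:.3g} Å² at {key}: inconsistent contexts"
            )
        rows.append({
            "chain": key[0], "res_seq": key[1], "i_code": key[2],
            "res_name": res_name,
            "sasa_unbound": u, "sasa_bound": b, "delta": max(d, 0.0),
        })
    return rows


def call_interface(table: list[dict], threshold: float = DEFAULT_THRESHOLD,
                   target: str = "", partners: Iterable[str] = ()) -> InterfaceSet:
    """Residues whose ΔSASA exceeds the threshold, in table order."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    chosen = [dict(r) for r in table if r["delta"] > threshold]
    tgt = target or (table[0]["chain"] if table else "")
    return InterfaceSet(
        target_chain=tgt, partner_chains=tuple(partners),
        residues=chosen, threshold=threshold,
    )


def sensitivity_report(table: list[dict],
                       thresholds: Sequence[float] = SENSITIVITY_THRESHOLDS) -> dict[float, int]:
    """Interface size at each threshold (monotone non-increasing)."""
    return {t: len(call_interface(table, t).residues) for t in thresholds}


def write_interface_tsv(iface: InterfaceSet, path) -> None:
    write_tsv(iface.residues, DELTA_TABLE_COLUMNS, path)


def pymol_selection(iface: InterfaceSet, name: str = "iface") -> str:
    """PyMOL-style selection string for visual checks."""
    nums = "+".join(str(n) for n in iface.residue_numbers())
    return f"select {name}, chain {iface.target_chain} and resi {nums}" if nums \
        else f"select {name}, none"
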