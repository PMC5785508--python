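"""Shrake-Rupley numerical solvent-accessible surface area (SASA).

The solvent-accessible surface of an atom is the sphere of radius
r_atom + r_probe traced by the centre of a spherical probe (water,
1.4 Å) rolled over the van der Waals surface.  The Shrake-Rupley
scheme estimates the accessible fraction of each such sphere by
scattering quasi-uniform test points on it and counting the points
that fall inside no neighbouring atom's expanded sphere:

    SASA_i = 4 * pi * (r_i + p)^2 * (accessible points / total points)

Two context modes matter for interface work: the neighbours can be
drawn from the selection itself (a chain in isolation, the "unbound"
state) or from the whole structure (the chain in its complex, the
"bound" state).  The difference per residue is the ΔSASA criterion
used for interface detection.

Tie rule: a test point strictly inside a neighbour's expanded sphere
(distance < r_neighbour + probe) is buried; boundary equality counts
as accessible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io_formats import AtomRecord, Structure

logger = logging.getLogger(__name__)

#: Van der Waals radii in Å.  Values are the conventional set used by
#: united-atom SASA tools; unknown elements fall back to the carbon
#: radius with a logged warning so that minimal coordinate files
#: without element columns remain usable.
DEFAULT_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_UNKNOWN_RADIUS = 1.70  # carbon fallback

PROBE_RADIUS = 1.4
N_POINTS = 960


@dataclass(frozen=True)
class RadiusTable:
    """Immutable element -> van der Waals radius lookup (Å)."""

    radii: tuple[tuple[str, float], ...] = tuple(sorted(DEFAULT_RADII.items()))
    default_radius: float = DEFAULT_UNKNOWN_RADIUS

    def __post_init__(self):
        for elem, r in self.radii:
            if not 0.5 < r < 3.0:
                raise ValueError(f"radius {r} for {elem!r} outside (0.5, 3.0) Å")
        if not 0.5 < self.default_radius < 3.0:
            raise ValueError("default radius outside (0.5, 3.0) Å")

    def radius(self, element: str) -> float:
        table = dict(self.radii)
        key = element.upper()
        if key in table:
            return table[key]
        logger.warning("unknown element %r: using default radius %.2f Å",
                       element, self.default_radius)
        return self.default_radius

    @classmethod
    def from_file(cls, path) -> "RadiusTable":
        """Load element<TAB>radius lines; '*' sets the default radius."""
        entries = {}
        default = DEFAULT_UNKNOWN_RADIUS
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                elem, r = line.split("\t")
                if elem == "*":
                    default = float(r)
                else:
                    entries[elem.upper()] = float(r)
        return cls(radii=tuple(sorted(entries.items())), default_radius=default)


@dataclass
class SasaProfile:
    """Per-atom and per-residue accessible areas for one selection."""

    per_atom: dict[int, float]  # atom index in structure order -> Å²
    per_residue: dict[tuple[str, int, str], float]  # residue key -> Å²
    probe_radius: float
    n_points: int
    selection: tuple[str, ...]  # chain ids of the selection

    @property
    def total(self) -> float:
        return float(sum(self.per_atom.values()))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    Golden-section spiral: latitudes are uniform in z, longitudes advance
    by the golden angle.  No randomness; identical output across runs.
    """
    if n < 12:
        raise ValueError("need at least 12 sphere points")
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = k * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return pts


def _coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([[a.x, a.y, a.z] for a in atoms], dtype=float)


def compute_sasa(
    structure: Structure,
    selection: Iterable[str] | None = None,
    probe_radius: float = PROBE_RADIUS,
    n_points: int = N_POINTS,
    radii: RadiusTable | None = None,
    context: str = "whole_structure",
) -> SasaProfile:
    """Shrake-Rupley SASA of the selected chains of a structure.

    selection
        Chain ids whose atoms are measured; None means all chains.
    context
        ``"selection_only"``: occluding neighbours are the selection's own
        atoms (the unbound state of a chain).  ``"whole_structure"``: all
        atoms of the structure occlude (the bound state).

    The neighbour search is exact: every atom pair closer than
    r_i + r_j + 2*probe is considered, nothing beyond is needed.
    """
    if context not in ("selection_only", "whole_structure"):
        raise ValueError(f"unknown context {context!r}")
    radii = radii or RadiusTable()
    chains = tuple(selection) if selection is not None else tuple(structure.chains)
    sel_atoms = structure.chain_atoms(chains)
    if not sel_atoms:
        raise ValueError("empty selection")
    ctx_atoms = sel_atoms if context == "selection_only" else structure.atoms

    sel_xyz = _coords(sel_atoms)
    ctx_xyz = _coords(ctx_atoms)
    if not np.isfinite(sel_xyz).all() or not np.isfinite(ctx_xyz).all():
        raise ValueError("non-finite atom coordinate")

    sel_r = np.array([radii.radius(a.element) for a in sel_atoms])
    ctx_r = np.array([radii.radius(a.element) for a in ctx_atoms])
    max_ctx_r = float(ctx_r.max())

    unit = sphere_points(n_points)
    tree = cKDTree(ctx_xyz)

    # map a context atom back to "is it the same atom as the selected one":
    # identity by object, since chain_atoms returns the structure's own records
    ctx_ids = [id(a) for a in ctx_atoms]

    per_atom: dict[int, float] = {}
    per_residue: dict[tuple[str, int, str], float] = {}
    for i, atom in enumerate(sel_atoms):
        ri = sel_r[i] + probe_radius
        pts = sel_xyz[i] + ri * unit  # (n_points, 3)
        # every context atom that could occlude any test point
        cutoff = sel_r[i] + max_ctx_r + 2.0 * probe_radius
        nb = tree.query_ball_point(sel_xyz[i], cutoff)
        nb = [j for j in nb if ctx_ids[j] != id(atom)]
        if nb:
            nb_xyz = ctx_xyz[nb]
            nb_rad = ctx_r[nb] + probe_radius
            d2 = np.sum((pts[:, None, :] - nb_xyz[None, :, :]) ** 2, axis=2)
            buried = (d2 < (nb_rad[None, :] ** 2)).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        area = 4.0 * math.pi * ri * ri * frac
        per_atom[i] = area
        key = atom.residue_key
        per_residue[key] = per_residue.get(key, 0.0) + area

    return SasaProfile(
        per_atom=per_atom, per_residue=per_residue,
        probe_radius=probe_radius, n_points=n_points, selection=chains,
    )


def residue_sasa(profile: SasaProfile, structure: Structure) -> list[dict]:
    """Per-residue table (chain, resnum, icode, resname, area) in file order."""
    rows = []
    for chain in profile.selection:
        for key, res_name in structure.residues(chain):
            if key in profile.per_residue:
                rows.append({
                    "chain": key[0], "res_seq": key[1], "i_code": key[2],
                    "res_name": res_name, "sasa": profile.per_residue[key],
                })
    return rows


# ---------------------------------------------------------------------------
# independent oracles, used by the test-suite and the acceptance script

def isolated_sphere_area(radius: float, probe: float = PROBE_RADIUS) -> float:
    """Closed-form SASA of a single atom with no neighbours."""
    r = radius + probe
    return 4.0 * math.pi * r * r


def two_sphere_area_analytic(r1: float, r2: float, d: float,
                             probe: float = PROBE_RADIUS) -> tuple[float, float]:
    """Exact SASA of two overlapping atoms via spherical-cap geometry.

    For expanded radii R1 = r1+p, R2 = r2+p at centre distance d, the
    cap of sphere 1 buried inside sphere 2 has height
    h1 = R1 - (d² + R1² - R2²) / (2d) and area 2·pi·R1·h1.
    Returns the accessible area of each sphere.
    """
    R1, R2 = r1 + probe, r2 + probe
    full1 = 4.0 * math.pi * R1 * R1
    full2 = 4.0 * math.pi * R2 * R2
    if d >= R1 + R2:
        return full1, full2
    if d + R1 <= R2:
        return 0.0, full2
    if d + R2 <= R1:
        return full1, 0.0
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2.0 * d)
    return full1 - 2.0 * math.pi * R1 * h1, full2 - 2.0 * math.pi * R2 * h2


def grid_sasa_oracle(xyz: np.ndarray, radii_: np.ndarray,
                     probe: float = PROBE_RADIUS, n_points: int = 20000,
                     seed: int = 0) -> np.ndarray:
    """Monte-Carlo SASA estimate, independent of the spiral quadrature.

    Uniform random directions per atom (Gaussian normalisation), same
    burial rule.  Used only as a cross-check oracle.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros(len(xyz))
    for i in range(len(xyz)):
        ri = radii_[i] + probe
        dirs = rng.normal(size=(n_points, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = xyz[i] + ri * dirs
        buried = np.zeros(n_points, dtype=bool)
        for j in range(len(xyz)):
            if j == i:
                continue
            rj = radii_[j] + probe
            buried |= np.sum((pts - xyz[j]) ** 2, axis=1) < rj * rj
        out[i] = 4.0 * math.pi * ri * ri * (1.0 - buried.mean())
    return out
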