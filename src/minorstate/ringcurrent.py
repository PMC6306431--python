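"""Haigh-Mallion ring-current shifts at amide nitrogen positions.

Aromatic side chains and nucleobases carry ring currents whose induced field
shifts nearby nuclei. The geometric factor for a nucleus at point P is

    G = sum over ring bonds (i, j) of s_ij * (1/r_i^3 + 1/r_j^3) / 2

where r_i is the distance from P to ring atom i and s_ij is the signed area
of the triangle formed by the projections of P and the bond into the ring
plane. G is positive on the ring axis (shielded region); the reported shift
is delta_rc = -scale_b * 1e6 * intensity * G ppm, so on-axis nuclei move
upfield. The proton-calibrated constant is applied unchanged to 15N
positions: the ring-current induced shift of a nitrogen is taken to be the
same in ppm as that of a proton at the same location.

The practical use here: when a nucleotide inhibitor binds, its base rings
shift nearby amide nitrogens; subtracting this purely geometric contribution
from observed free->bound shift differences isolates the conformational
part, which is what the dispersion-derived shift differences should match
under conformational selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .structures import StructureModel

__all__ = [
    "RingDefinition",
    "load_ring_definitions",
    "haigh_mallion_G",
    "find_rings",
    "amide_nitrogen_shifts",
    "correct_binding_shifts",
]

#: Default proton-calibrated scale constant (dimensionless shielding per A^-3).
DEFAULT_SCALE_B = 5.455e-6

#: Points closer than this (Å) to any ring atom are inside van der Waals
#: contact; the geometric factor diverges and the result is unreliable.
MIN_RELIABLE_DISTANCE = 1.0

MAX_OUT_OF_PLANE = 0.5  # Å; warn above this


@dataclass(frozen=True)
class RingDefinition:
    resname: str
    name: str  # "five" / "six"
    atoms: tuple[str, ...]
    intensity: float


def load_ring_definitions(path=None) -> tuple[float, list[RingDefinition]]:
    """(scale_b, ring definitions) from a YAML parameter file.

    Defaults to the packaged table (benzene-relative intensity factors for
    aromatic side chains and nucleobases).
    """
    if path is None:
        text = resources.files("minorstate").joinpath("data/ring_params.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    rings = [RingDefinition(resname=r["resname"], name=r.get("name", "ring"),
                            atoms=tuple(r["atoms"]), intensity=float(r["intensity"]))
             for r in raw["rings"]]
    return float(raw.get("scale_b", DEFAULT_SCALE_B)), rings


def _ring_plane(ring_coords: np.ndarray):
    """(center, unit normal, max out-of-plane distance) of a ring."""
    center = ring_coords.mean(axis=0)
    rel = ring_coords - center
    _, _, vt = np.linalg.svd(rel)
    normal = vt[2]
    out_of_plane = float(np.max(np.abs(rel @ normal)))
    return center, normal, out_of_plane


def haigh_mallion_G(ring_coords: np.ndarray, point: np.ndarray) -> float:
    """Geometric ring-current factor (Å^-3) at *point*.

    Ring atoms must be given in bond order around the ring (>= 5 atoms,
    approximately coplanar). The sign does not depend on the traversal
    direction: flipping it flips both the normal and the signed areas.
    """
    ring_coords = np.asarray(ring_coords, dtype=float)
    point = np.asarray(point, dtype=float)
    n = len(ring_coords)
    if n < 5:
        raise ValueError("ring needs at least 5 atoms")
    center, normal, oop = _ring_plane(ring_coords)
    if oop > MAX_OUT_OF_PLANE:
        warnings.warn(f"ring atoms deviate {oop:.2f} Å from the best plane")
    # right-handed normal relative to the traversal, so G > 0 on the axis
    circ = np.cross(ring_coords[1] - ring_coords[0], ring_coords[2] - ring_coords[1])
    if circ @ normal < 0:
        normal = -normal
    # project everything into the ring plane
    proj = ring_coords - np.outer((ring_coords - center) @ normal, normal)
    p_proj = point - ((point - center) @ normal) * normal
    r = np.linalg.norm(ring_coords - point, axis=1)
    g = 0.0
    for i in range(n):
        j = (i + 1) % n
        s_ij = 0.5 * np.cross(proj[i] - p_proj, proj[j] - p_proj) @ normal
        g += s_ij * (1.0 / r[i] ** 3 + 1.0 / r[j] ** 3) / 2.0
    return float(g)


def find_rings(structure: StructureModel, rings: list[RingDefinition]):
    """All ring instances present in the structure.

    Returns a list of dicts with keys chain, resnum, resname, ring (the
    RingDefinition) and coords; rings with missing member atoms are skipped
    with a warning.
    """
    found = []
    residues: dict[tuple, dict[str, np.ndarray]] = {}
    resnames: dict[tuple, str] = {}
    for i in range(structure.n_atoms):
        key = (structure.chain[i], structure.resnum[i])
        residues.setdefault(key, {})[structure.atom_name[i]] = structure.coords[i]
        resnames[key] = structure.resname[i]
    defs_by_resname: dict[str, list[RingDefinition]] = {}
    for rd in rings:
        defs_by_resname.setdefault(rd.resname, []).append(rd)
    for key, atoms in residues.items():
        for rd in defs_by_resname.get(resnames[key], []):
            missing = [a for a in rd.atoms if a not in atoms]
            if missing:
                warnings.warn(
                    f"{resnames[key]} {key}: ring {rd.name} missing atoms "
                    f"{missing}; skipped")
                continue
            found.append({
                "chain": key[0], "resnum": int(key[1]), "resname": resnames[key],
                "ring": rd, "coords": np.array([atoms[a] for a in rd.atoms]),
            })
    return found


def amide_nitrogen_shifts(structure: StructureModel,
                          rings: list[RingDefinition] | None = None,
                          scale_b: float | None = None,
                          target_atom_names: tuple[str, ...] = ("N",)) -> dict:
    """Ring-current shift (ppm) at every backbone amide nitrogen.

    Returns a dict keyed by (chain, resnum) with fields shift_ppm,
    dominant_ring (the ring contributing the largest magnitude) and
    reliable (False when the nitrogen sits within van der Waals contact of
    a ring atom). *target_atom_names* widens the targets to arbitrary atoms
    (e.g. ("H",) to validate against proton conventions).
    """
    if rings is None or scale_b is None:
        default_b, default_rings = load_ring_definitions()
        rings = default_rings if rings is None else rings
        scale_b = default_b if scale_b is None else scale_b
    instances = find_rings(structure, rings)
    mask = np.isin(np.asarray(structure.atom_name, dtype=str), target_atom_names)
    out: dict[tuple, dict] = {}
    for i in np.flatnonzero(mask):
        point = structure.coords[i]
        total = 0.0
        dominant, dominant_abs = None, 0.0
        reliable = True
        for inst in instances:
            dmin = float(np.min(np.linalg.norm(inst["coords"] - point, axis=1)))
            if dmin < MIN_RELIABLE_DISTANCE:
                reliable = False
            g = haigh_mallion_G(inst["coords"], point)
            contrib = -scale_b * 1e6 * inst["ring"].intensity * g
            total += contrib
            if abs(contrib) > dominant_abs:
                dominant_abs = abs(contrib)
                dominant = f'{inst["resname"]}{inst["resnum"]}:{inst["ring"].name}'
        key = (structure.chain[i], int(structure.resnum[i]))
        out[key] = {"shift_ppm": total, "dominant_ring": dominant,
                    "reliable": reliable,
                    "atom_name": str(structure.atom_name[i])}
    return out


def correct_binding_shifts(observed_delta: dict, ring_shifts: dict):
    """Subtract the bound-state-only ring-current contribution from observed
    free->bound shift differences.

    Keys are residue identifiers (matched exactly). Returns (corrected dict,
    unmatched list); unmatched residues pass through uncorrected and are
    flagged rather than dropped.
    """
    corrected = {}
    unmatched = []
    for key, obs in observed_delta.items():
        if key in ring_shifts:
            ring = ring_shifts[key]
            ring_val = ring["shift_ppm"] if isinstance(ring, dict) else float(ring)
            corrected[key] = obs - ring_val
        else:
            corrected[key] = obs
            unmatched.append(key)
    return corrected, unmatched
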