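"""Elastic-network normal-mode analysis and mode-trajectory RMSD profiling.

The structure is modeled as point masses joined by harmonic springs between
all heavy-atom pairs within a cutoff (default 10 Å). Spring constants decay
with distance as exp(-(r/r_w)^2) with r_w the distance-weight parameter
(default 5 Å); a pure-cutoff (uniform spring) network is available via
``distance_weight=None``. Masses are uniform: only mode shapes and their
ordering are used downstream, not absolute frequencies.

The low-frequency modes of such a network capture the collective motions
allowed by the architecture of the structure - for a two-lobed protein,
hinge bending and twisting. A mode trajectory displaces the structure along
one eigenvector, rescaled so the mean all-atom RMSD from the starting
structure over the frames hits a target (default 1.0 Å); profiling the
superposed RMSD of those frames against a reference structure (optionally on
an atom subset such as the Cbeta atoms of active-site lip residues) tests
whether the mode carries the structure toward that reference: an interior
minimum of the profile is the facilitation signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .structures import StructureModel

__all__ = [
    "ElasticNetwork",
    "ModeSet",
    "ModeTrajectory",
    "build_network",
    "compute_modes",
    "mode_trajectory",
    "kabsch_rmsd",
    "trajectory_rmsd_profile",
    "find_min_amplitude",
    "mode_overlap",
]

N_RIGID_BODY_MODES = 6


@dataclass
class ElasticNetwork:
    coords: np.ndarray  # (N, 3) Å
    pairs: np.ndarray  # (M, 2) int indices, i < j
    spring_constants: np.ndarray  # (M,) dimensionless
    cutoff: float
    distance_weight: float | None


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # (3N, k) columns, orthonormal
    n_zero_modes: int
    n_atoms: int

    def mode(self, index: int) -> np.ndarray:
        """Eigenvector as an (N, 3) displacement field. 1-based *index* with
        modes 1..6 the rigid-body modes, 7 the lowest internal mode."""
        return self.eigenvectors[:, index - 1].reshape(self.n_atoms, 3)


@dataclass
class ModeTrajectory:
    structure: StructureModel
    mode_index: int
    amplitudes: np.ndarray
    frames: list[StructureModel]
    rescale: float


def build_network(structure: StructureModel, cutoff: float = 10.0,
                  distance_weight: float | None = 5.0) -> ElasticNetwork:
    """Spring network over all atom pairs with r_ij <= cutoff.

    Spring constant exp(-(r/distance_weight)^2), or 1 for every contact when
    distance_weight is None (Tirion springs). Raises if the network is not a
    single connected component.
    """
    coords = structure.coords
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 atoms")
    d = pdist(coords)
    dm = squareform(d)
    iu, ju = np.triu_indices(n, k=1)
    within = dm[iu, ju] <= cutoff
    pairs = np.column_stack([iu[within], ju[within]])
    r = dm[iu, ju][within]
    if distance_weight is None:
        k = np.ones_like(r)
    else:
        k = np.exp(-((r / distance_weight) ** 2))
    adj = np.zeros((n, n), dtype=bool)
    adj[pairs[:, 0], pairs[:, 1]] = True
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"elastic network is disconnected: {n_comp} components with sizes "
            f"{sorted(sizes, reverse=True)} at cutoff {cutoff} Å"
        )
    return ElasticNetwork(coords=coords, pairs=pairs, spring_constants=k,
                          cutoff=cutoff, distance_weight=distance_weight)


def hessian(net: ElasticNetwork) -> np.ndarray:
    """3N x 3N anisotropic-network Hessian.

    Off-diagonal block for pair (i, j): -k * d d^T with d the unit bond
    vector; diagonal blocks are the negative sum of the off-diagonal blocks
    in the row, so rigid translations are exactly in the null space.
    """
    n = len(net.coords)
    H = np.zeros((3 * n, 3 * n))
    for (i, j), k in zip(net.pairs, net.spring_constants):
        dvec = net.coords[j] - net.coords[i]
        r2 = dvec @ dvec
        block = k * np.outer(dvec, dvec) / r2
        H[3 * i:3 * i + 3, 3 * j:3 * j + 3] -= block
        H[3 * j:3 * j + 3, 3 * i:3 * i + 3] -= block
        H[3 * i:3 * i + 3, 3 * i:3 * i + 3] += block
        H[3 * j:3 * j + 3, 3 * j:3 * j + 3] += block
    return H


def spring_energy(net: ElasticNetwork, coords: np.ndarray) -> float:
    """Harmonic energy 1/2 sum k (|r_ij| - |r_ij^0|)^2 of a displaced frame."""
    i, j = net.pairs[:, 0], net.pairs[:, 1]
    r0 = np.linalg.norm(net.coords[j] - net.coords[i], axis=1)
    r = np.linalg.norm(coords[j] - coords[i], axis=1)
    return float(0.5 * np.sum(net.spring_constants * (r - r0) ** 2))


def compute_modes(net: ElasticNetwork, n_modes: int | None = None,
                  dense_max_atoms: int = 3000, zero_tol: float = 1e-8) -> ModeSet:
    """Eigendecomposition of the Hessian; modes sorted ascending.

    A connected 3D network has exactly 6 zero modes (rigid translations and
    rotations); more indicates degenerate geometry (e.g. collinear atoms)
    and raises. Dense symmetric solver by default; truncated lowest-k
    (default 26) for structures above *dense_max_atoms* atoms.
    """
    n = len(net.coords)
    H = hessian(net)
    if n <= dense_max_atoms and n_modes is None:
        w, v = np.linalg.eigh(H)
    else:
        from scipy.sparse.linalg import eigsh

        k = n_modes if n_modes is not None else 26
        w, v = eigsh(H, k=min(k, 3 * n - 1), sigma=0, which="LM")
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    lam_max = float(np.max(np.abs(w)))
    n_zero = int(np.sum(np.abs(w) < zero_tol * lam_max))
    if n_zero > N_RIGID_BODY_MODES:
        raise ValueError(
            f"{n_zero} near-zero modes (expected 6): degenerate geometry "
            "(e.g. collinear chain)"
        )
    if n_zero < N_RIGID_BODY_MODES:
        # zero modes split only by numerical round-off; keep the canonical 6
        n_zero = N_RIGID_BODY_MODES
    return ModeSet(eigenvalues=w, eigenvectors=v, n_zero_modes=n_zero, n_atoms=n)


def mode_trajectory(structure: StructureModel, modes: ModeSet, mode_index: int,
                    n_frames: int = 8, rescale: float = 1.0) -> ModeTrajectory:
    """Frames X(a) = X0 + a*v along one internal mode (1-based index > 6).

    Amplitudes are symmetric about 0 and uniformly spaced, scaled so the
    mean all-atom RMSD of the frames to the start equals *rescale* Å. For a
    unit eigenvector RMSD(X(a), X0) = |a| / sqrt(N) exactly.
    """
    if mode_index <= N_RIGID_BODY_MODES:
        raise ValueError(f"mode {mode_index} is a rigid-body mode; use index > 6")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    v = modes.mode(mode_index)
    n = modes.n_atoms
    rel = np.linspace(-1.0, 1.0, n_frames)
    # mean RMSD over frames = A * mean|rel| / sqrt(N) = rescale
    amp_max = rescale * np.sqrt(n) / np.mean(np.abs(rel))
    amplitudes = amp_max * rel
    frames = [structure.with_coords(structure.coords + a * v,
                                    source=f"{structure.source}|mode{mode_index}|a={a:.4f}")
              for a in amplitudes]
    return ModeTrajectory(structure=structure, mode_index=mode_index,
                          amplitudes=amplitudes, frames=frames, rescale=rescale)


def _kabsch(p: np.ndarray, q: np.ndarray):
    """Optimal rotation/translation mapping p onto q (least squares)."""
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    p0, q0 = p - pc, q - qc
    h = p0.T @ q0
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    d = np.diag([1.0, 1.0, sign])
    rot = vt.T @ d @ u.T
    trans = qc - rot @ pc
    return rot, trans


def kabsch_rmsd(a: StructureModel, b: StructureModel,
                selection: dict | None = None):
    """Least-squares superposition RMSD between matched atoms of a and b.

    selection: optional dict with keys ``atom_names`` and/or ``resnums``
    restricting the atoms used (e.g. {"atom_names": ["CB"], "resnums":
    [42, 56]}). Atoms are matched by (chain, resnum, atom_name); unmatched
    atoms are reported in the error if fewer than 3 remain.

    Returns (rmsd, rotation, translation) with rotation/translation mapping
    a onto b.
    """
    if selection:
        a = a.select_atoms(selection.get("atom_names"), selection.get("resnums"))
        b = b.select_atoms(selection.get("atom_names"), selection.get("resnums"))
    ia, ib, unmatched = a.match(b)
    if len(ia) < 3:
        raise ValueError(
            f"only {len(ia)} matched atoms (need >=3); unmatched keys e.g. "
            f"{unmatched[:5]}"
        )
    p, q = a.coords[ia], b.coords[ib]
    rot, trans = _kabsch(p, q)
    diff = (p @ rot.T + trans) - q
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return rmsd, rot, trans


def trajectory_rmsd_profile(traj: ModeTrajectory, reference: StructureModel,
                            selection: dict | None = None,
                            superpose_on_selection: bool = False):
    """Superposed RMSD of each trajectory frame against a reference.

    The superposition is computed on all atoms common to frame and
    reference; the RMSD is then evaluated on *selection* (all common atoms
    when None). With superpose_on_selection=True the superposition itself is
    restricted to the selection.

    Returns a list of (amplitude, rmsd).
    """
    profile = []
    for a, frame in zip(traj.amplitudes, traj.frames):
        if superpose_on_selection:
            rmsd, _, _ = kabsch_rmsd(frame, reference, selection)
        else:
            _, rot, trans = kabsch_rmsd(frame, reference, None)
            fsel = frame.select_atoms((selection or {}).get("atom_names"),
                                      (selection or {}).get("resnums"))
            rsel = reference.select_atoms((selection or {}).get("atom_names"),
                                          (selection or {}).get("resnums"))
            ia, ib, _ = fsel.match(rsel)
            if len(ia) == 0:
                raise ValueError("selection matches no atoms")
            diff = (fsel.coords[ia] @ rot.T + trans) - rsel.coords[ib]
            rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
        profile.append((float(a), rmsd))
    return profile


def find_min_amplitude(profile) -> tuple[float, float, bool]:
    """Discrete minimizer of an (amplitude, rmsd) profile with parabolic
    refinement through the bracketing triple.

    Returns (a_star, rmsd_min, is_interior); is_interior is False when the
    minimum sits at either end of the amplitude range (no facilitation
    signal).
    """
    if len(profile) < 3:
        raise ValueError("need at least 3 profile points")
    a = np.array([p[0] for p in profile])
    r = np.array([p[1] for p in profile])
    order = np.argsort(a)
    a, r = a[order], r[order]
    i = int(np.argmin(r))
    if i == 0 or i == len(a) - 1:
        return float(a[i]), float(r[i]), False
    x0, x1, x2 = a[i - 1:i + 2]
    y0, y1, y2 = r[i - 1:i + 2]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    acoef = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    bcoef = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if acoef <= 0:
        return float(a[i]), float(r[i]), True
    a_star = -bcoef / (2 * acoef)
    c = (y0 - acoef * x0**2 - bcoef * x0)
    r_star = acoef * a_star**2 + bcoef * a_star + c
    return float(a_star), float(min(r_star, r[i])), True


def mode_overlap(modes: ModeSet, mode_index: int, displacement: np.ndarray) -> float:
    """Squared overlap (normalized dot product squared) between one mode and a
    displacement field of shape (N, 3)."""
    v = modes.mode(mode_index).ravel()
    d = np.asarray(displacement, dtype=float).ravel()
    d = d / np.linalg.norm(d)
    return float((v @ d) ** 2 / (v @ v))
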