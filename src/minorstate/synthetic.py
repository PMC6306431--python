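"""Synthetic-data generators with the statistical structure the analyses assume.

Three generators:

* shift surfaces: per-residue amide shifts on a (temperature x [Gdm]) grid
  from two-state fast-exchange averaging over a ground and a low-lying
  excited state, with linear temperature baselines (about -4.5 ppb/K) and
  peak-position noise of 0.0075 ppm;
* CPMG dispersion datasets: two-field (600/800 MHz) R2eff profiles from the
  Bloch-McConnell forward model with Gaussian noise (0.2 s^-1 default);
* hinged two-lobe toy structures: an open/closed pair related by a rotation
  about a hinge axis, plus a target part-way along the closure with added
  jitter, for exercising the normal-mode facilitation analysis.

Every generator takes a seeded config and returns ground truth alongside
the data, so parameter-recovery tests need no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np

from .capsid import ShiftSeries
from .dispersion import DispersionSeries, TwoSiteModel, simulate_profile
from .structures import StructureModel

__all__ = [
    "ShiftSurfaceConfig",
    "DispersionSimConfig",
    "HingeSimConfig",
    "gen_shift_surfaces",
    "gen_dispersion_dataset",
    "gen_hinge_structures",
    "excited_population",
]

#: Gas constant, kJ/mol/K.
R_GAS = 0.0083145

_DEFAULT_TEMPERATURES = tuple(np.arange(288.0, 313.1, 5.0))  # 288..313 K every 5
_DEFAULT_GDM = (0.0, 0.4, 0.8, 1.2, 1.6)  # M


def _draw(rng: np.random.Generator, value, random_sign: bool = False) -> float:
    """A scalar config value, or a uniform draw from a (lo, hi) range."""
    if np.isscalar(value):
        v = float(value)
    else:
        lo, hi = value
        v = float(rng.uniform(lo, hi))
    if random_sign and rng.random() < 0.5:
        v = -v
    return v


@dataclass
class ShiftSurfaceConfig:
    """Conditions for the shift-surface generator.

    Scalar fields may instead be (lo, hi) ranges sampled once per excited
    residue. The two-state thermodynamics is dG(T, g) = dH - T*dS - m_gdm*g
    with dS derived from dG0 at 298 K when not given explicitly; the
    denaturant term uses the standard linear m-value model (the denaturant
    destabilizes the ground state relative to the excited state).
    """

    n_residues: int = 100
    temperatures: tuple = _DEFAULT_TEMPERATURES
    gdm_levels: tuple = _DEFAULT_GDM
    baseline_slope: float | tuple = -0.0045  # ppm/K
    noise_sd: float = 0.0075  # ppm
    excited_fraction_of_residues: float = 0.16
    dG0: float | tuple = (6.0, 7.5)  # kJ/mol, ground -> excited at 298 K
    dH: float | tuple = (-75.0, -55.0)  # kJ/mol; compact excited state: dH < 0, dS < 0
    dH_sign_random: bool = False
    dS: float | None = None  # kJ/mol/K; derived from dG0 and dH when None
    m_gdm: float | tuple = (2.0, 2.8)  # kJ/mol/M
    delta_shift: float | tuple = (2.0, 3.5)  # ppm magnitude, excited - ground
    delta_shift_sign_random: bool = True
    base_shift: tuple = (7.5, 9.0)  # ppm, ground-state shift at the grid center
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if len(t) < 3 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing, >=3 values")
        g = np.asarray(self.gdm_levels, dtype=float)
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("gdm_levels must be non-negative increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.excited_fraction_of_residues <= 1:
            raise ValueError("excited_fraction_of_residues must be in [0, 1]")


def excited_population(dH: float, dS: float, m_gdm: float,
                       temperature, gdm) -> np.ndarray:
    """Two-state excited population p_E = 1 / (1 + exp(dG / RT)) with
    dG(T, g) = dH - T*dS - m_gdm*g (kJ/mol)."""
    t = np.asarray(temperature, dtype=float)
    g = np.asarray(gdm, dtype=float)
    dg = dH - t * dS - m_gdm * g
    return 1.0 / (1.0 + np.exp(dg / (R_GAS * t)))


def _thermo_params(rng, cfg: ShiftSurfaceConfig):
    dh = _draw(rng, cfg.dH, random_sign=cfg.dH_sign_random)
    dg0 = _draw(rng, cfg.dG0)
    ds = cfg.dS if cfg.dS is not None else (dh - dg0) / 298.0
    m = _draw(rng, cfg.m_gdm)
    return dh, ds, m


def gen_shift_surfaces(cfg: ShiftSurfaceConfig):
    """Generate per-residue shift series plus ground truth.

    Observed shift: delta(T, g) = delta_G(T) + p_E(T, g) * ddelta + noise,
    with delta_G(T) = delta0 + baseline_slope * (T - 298). Residues outside
    the excited fraction get ddelta = 0 (pure linear baselines). Any
    parameter set whose p_E exceeds 0.5 somewhere on the grid is rejected
    (the excited state must stay minor); sampled per-residue parameters are
    redrawn until valid.

    Returns (list of ShiftSeries, ground_truth dict keyed by residue id).
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.asarray(cfg.temperatures, dtype=float)
    g = np.asarray(cfg.gdm_levels, dtype=float)
    tt, gg = np.meshgrid(t, g, indexing="ij")
    n_excited = int(round(cfg.excited_fraction_of_residues * cfg.n_residues))
    explicit_thermo = (np.isscalar(cfg.dH) and not cfg.dH_sign_random
                       and np.isscalar(cfg.dG0) and np.isscalar(cfg.m_gdm))
    series: list[ShiftSeries] = []
    truth: dict[str, dict] = {}
    for i in range(cfg.n_residues):
        rid = f"R{i + 1}"
        delta0 = _draw(rng, cfg.base_shift)
        slope = _draw(rng, cfg.baseline_slope)
        is_excited = i < n_excited
        if is_excited:
            for attempt in range(200):
                dh, ds, m = _thermo_params(rng, cfg)
                p_e = excited_population(dh, ds, m, tt, gg)
                if np.max(p_e) <= 0.5:
                    break
                if explicit_thermo:
                    raise ValueError(
                        f"excited population exceeds 0.5 on the grid (max "
                        f"{np.max(p_e):.3f}); the excited state must stay minor"
                    )
            else:
                raise ValueError("could not sample a valid minor-state parameter set")
            ddelta = _draw(rng, cfg.delta_shift,
                           random_sign=cfg.delta_shift_sign_random)
        else:
            dh = ds = m = 0.0
            ddelta = 0.0
            p_e = np.zeros_like(tt)
        clean = delta0 + slope * (tt - 298.0) + p_e * ddelta
        noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape) \
            if cfg.noise_sd > 0 else clean
        records = [(float(tt[a, b]), float(gg[a, b]), float(noisy[a, b]))
                   for a in range(tt.shape[0]) for b in range(tt.shape[1])]
        series.append(ShiftSeries(residue_id=rid, records=records))
        truth[rid] = {
            "excited": bool(is_excited), "delta0": delta0, "baseline_slope": slope,
            "dH": dh, "dS": ds, "m_gdm": m, "delta_shift": ddelta,
        }
    return series, truth


@dataclass
class DispersionSimConfig:
    """Conditions for the CPMG dispersion generator.

    residues: list of (id, delta_omega_ppm, {field: r2_base}); the default
    emulates a free-enzyme regime of six residues with shift differences of
    1.5-4 ppm and a global exchange rate of 750 s^-1 at 2% minor population.
    """

    kex: float = 750.0
    p_b: float = 0.02
    fields: tuple = (600.0, 800.0)
    residues: list = dataclass_field(default_factory=lambda: [
        (f"R{i + 1}", dw, {600.0: 17.0 + 0.5 * i, 800.0: 19.0 + 0.5 * i})
        for i, dw in enumerate([0.8, 1.0, 1.2, 1.4, 1.6, 2.0])
    ])
    t_cpmg: float = 0.040  # s
    nu_grid: tuple = tuple(np.arange(50.0, 751.0, 50.0))  # Hz
    noise_sd: float = 0.2  # s^-1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_b < 0.5:
            raise ValueError("p_b must lie in (0, 0.5)")
        if not self.kex > 0 or not self.t_cpmg > 0:
            raise ValueError("kex and t_cpmg must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_dispersion_dataset(cfg: DispersionSimConfig):
    """Two-field dispersion series from the Bloch-McConnell forward model.

    Noiseless R2eff comes from the same propagator used in fitting; Gaussian
    noise of sd noise_sd is then added. The per-point error column is set to
    noise_sd (1.0 when noiseless, so chi-square is still defined).

    Returns (list of DispersionSeries, TwoSiteModel ground truth).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = TwoSiteModel(
        kex=cfg.kex, p_b=cfg.p_b,
        delta_omega={rid: dw for rid, dw, _ in cfg.residues},
        r2_base={(rid, f): r2[f] for rid, _, r2 in cfg.residues for f in cfg.fields},
    )
    nu = np.asarray(cfg.nu_grid, dtype=float)
    err_val = cfg.noise_sd if cfg.noise_sd > 0 else 1.0
    dataset = []
    for rid, _, _ in cfg.residues:
        for f in cfg.fields:
            clean = simulate_profile(truth, rid, f, nu, cfg.t_cpmg)
            noisy = clean + rng.normal(0.0, cfg.noise_sd, size=clean.shape) \
                if cfg.noise_sd > 0 else clean
            dataset.append(DispersionSeries(
                residue_id=rid, field=f, nu_cpmg=nu, r2eff=noisy,
                err=np.full_like(nu, err_val)))
    return dataset, truth


@dataclass
class HingeSimConfig:
    """Toy two-lobe hinged structure.

    Two flattened ellipsoidal lobes of *atoms_per_lobe* atoms sit at
    +/- lobe_separation/2 along x, joined by a short strut of atoms along
    the hinge (z) axis. Springs to atoms on the rotation axis are invariant
    under rotation about it, so the in-plane hinge bend is the softest
    internal mode of the network by construction.
    """

    atoms_per_lobe: int = 24
    lobe_separation: float = 14.0  # Å
    lobe_half_extent: tuple = (3.5, 2.5, 1.0)  # Å, (x, y, z)
    n_hinge_atoms: int = 5
    hinge_half_span: float = 3.0  # Å along z
    hinge_angle_closed: float = 20.0  # degrees
    intermediate_fraction: float = 0.4
    jitter_sd: float = 0.05  # Å; below crystallographic coordinate precision
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atoms_per_lobe < 4:
            raise ValueError("atoms_per_lobe must be >= 4")
        if not 0 <= self.intermediate_fraction <= 1:
            raise ValueError("intermediate_fraction must lie in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def _rot_z(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _hinge_coords(cfg: HingeSimConfig, rng: np.random.Generator):
    half = np.asarray(cfg.lobe_half_extent, dtype=float)
    sep = cfg.lobe_separation / 2.0
    lobe_a = rng.uniform(-1, 1, size=(cfg.atoms_per_lobe, 3)) * half + [sep, 0, 0]
    lobe_b = rng.uniform(-1, 1, size=(cfg.atoms_per_lobe, 3)) * half + [-sep, 0, 0]
    hz = np.linspace(-cfg.hinge_half_span, cfg.hinge_half_span, cfg.n_hinge_atoms)
    strut = np.column_stack([np.zeros_like(hz), np.zeros_like(hz), hz])
    coords = np.vstack([strut, lobe_a, lobe_b])
    moving = np.zeros(len(coords), dtype=bool)
    moving[cfg.n_hinge_atoms + cfg.atoms_per_lobe:] = True  # lobe B rotates
    return coords, moving


def _as_structure(coords: np.ndarray, source: str) -> StructureModel:
    n = len(coords)
    return StructureModel(
        chain=np.full(n, "A", dtype=object),
        resnum=np.arange(1, n + 1),
        resname=np.full(n, "GLY", dtype=object),
        atom_name=np.full(n, "CA", dtype=object),
        element=np.full(n, "C", dtype=object),
        coords=coords,
        source=source,
    )


def rotate_lobe(structure: StructureModel, moving: np.ndarray,
                theta_deg: float) -> StructureModel:
    """Rotate the flagged atoms about the z axis through the origin."""
    coords = structure.coords.copy()
    coords[moving] = coords[moving] @ _rot_z(theta_deg).T
    return structure.with_coords(coords, source=f"{structure.source}|rot{theta_deg:g}")


def gen_hinge_structures(cfg: HingeSimConfig):
    """(open, closed, target, info) synthetic hinge structures.

    closed rotates one lobe by hinge_angle_closed about the hinge axis;
    target rotates by intermediate_fraction * angle and adds independent
    Gaussian jitter (the stand-in for a closure component that pure hinge
    bending cannot produce). info carries the moving-atom mask and angles.
    """
    rng = np.random.default_rng(cfg.seed)
    coords, moving = _hinge_coords(cfg, rng)
    open_s = _as_structure(coords, "hinge-open")
    closed_s = rotate_lobe(open_s, moving, cfg.hinge_angle_closed)
    target_angle = cfg.intermediate_fraction * cfg.hinge_angle_closed
    tgt = rotate_lobe(open_s, moving, target_angle)
    if cfg.jitter_sd > 0:
        tgt = tgt.with_coords(
            tgt.coords + rng.normal(0.0, cfg.jitter_sd, size=tgt.coords.shape))
    tgt.source = "hinge-target"
    closed_s.source = "hinge-closed"
    info = {"moving_mask": moving, "closed_angle": cfg.hinge_angle_closed,
            "target_angle": target_angle}
    return open_s, closed_s, tgt, info
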