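"""Two-site CPMG relaxation dispersion: forward model and fitting.

The forward model propagates the transverse magnetization of a two-site
exchanging spin system (ground state A, minor excited state B) through an
ideal CPMG echo train by explicit numerical evolution of the Bloch-McConnell
equations. The effective relaxation rate measured in a constant-time CPMG
experiment is

    R2eff(nu_cpmg) = -(1/T_cpmg) * ln(I_cpmg / I0)

and the exchange contribution Rex = R2eff - R2(base) is progressively
refocused as the pulse rate nu_cpmg increases, which encodes the exchange
rate kex = k_forward + k_back, the minor population p_B, and the chemical
shift difference between the states (here 15N, so it scales with the static
field).

Fitting follows the standard global strategy: all residues at both static
fields share one kex and one p_B (equivalently one forward and one back
rate), while each residue keeps its own |delta omega| and its own
exchange-free R2 per field. chi-square profiling over a fixed forward rate
k_f = p_B*kex provides a robust interval for the slow forward step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAMMA_RATIO_15N",
    "DispersionSeries",
    "TwoSiteModel",
    "FitResult",
    "AlphaEstimate",
    "compute_r2eff",
    "simulate_r2eff",
    "simulate_profile",
    "luz_meiboom_rex",
    "echo_counts",
    "select_residues",
    "fit_single_residue",
    "fit_global",
    "profile_forward_rate",
    "compute_alpha",
    "correlate_with_binding_shifts",
    "rates_from_populations",
    "population_from_rates",
]

#: 15N Larmor frequency as a fraction of the 1H frequency (field in 1H MHz).
GAMMA_RATIO_15N = 0.101329

#: Default per-point R2eff uncertainties (s^-1) by 1H field in MHz, used when
#: a dispersion table carries no explicit error column.
DEFAULT_R2EFF_ERRORS = {600.0: 0.7, 800.0: 1.4}
FALLBACK_R2EFF_ERROR = 0.2


@dataclass
class DispersionSeries:
    """Per-residue, per-field R2eff(nu_cpmg) with uncertainties."""

    residue_id: str
    field: float  # 1H MHz
    nu_cpmg: np.ndarray  # Hz
    r2eff: np.ndarray  # s^-1
    err: np.ndarray  # s^-1
    valid: np.ndarray | None = None  # False marks points flagged bad upstream

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.err = np.asarray(self.err, dtype=float)
        if self.valid is None:
            self.valid = np.ones_like(self.nu_cpmg, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.nu_cpmg) == len(self.r2eff) == len(self.err) == len(self.valid)):
            raise ValueError("nu_cpmg, r2eff, err, valid must have equal length")
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg must be positive")
        if np.any(self.err[self.valid] <= 0):
            raise ValueError("errors must be positive")

    def good(self) -> "DispersionSeries":
        """Series restricted to valid points."""
        m = self.valid
        return DispersionSeries(self.residue_id, self.field, self.nu_cpmg[m],
                                self.r2eff[m], self.err[m])

    @property
    def span(self) -> float:
        """max(R2eff) - min(R2eff), the magnitude of the dispersion."""
        r = self.r2eff[self.valid]
        return float(np.max(r) - np.min(r))


@dataclass
class TwoSiteModel:
    """Global two-site exchange parameters plus per-residue quantities.

    kex is the sum of forward and back rates; p_b the minor population.
    delta_omega is stored in ppm (magnitude unless a sign is known);
    r2_base maps (residue_id, field) -> exchange-free R2 in s^-1, assumed
    identical at both exchange sites.
    """

    kex: float
    p_b: float
    delta_omega: dict[str, float] = dataclass_field(default_factory=dict)
    r2_base: dict[tuple[str, float], float] = dataclass_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.kex > 0:
            raise ValueError("kex must be positive")
        if not 0 <= self.p_b < 0.5:
            raise ValueError("p_b must lie in [0, 0.5)")
        for key, r2 in self.r2_base.items():
            if not r2 > 0:
                raise ValueError(f"r2_base must be positive (residue {key})")

    @property
    def k_forward(self) -> float:
        return self.p_b * self.kex

    @property
    def k_back(self) -> float:
        return (1.0 - self.p_b) * self.kex


@dataclass
class FitResult:
    model: TwoSiteModel
    chi2: float
    n_data: int
    n_params: int
    param_sd: dict = dataclass_field(default_factory=dict)
    excluded_residues: dict = dataclass_field(default_factory=dict)
    converged: bool = True

    @property
    def reduced_chi2(self) -> float:
        dof = self.n_data - self.n_params
        return self.chi2 / dof if dof > 0 else np.inf


@dataclass
class AlphaEstimate:
    per_residue: dict[str, float]
    mean: float
    sd: float
    skipped: dict[str, str] = dataclass_field(default_factory=dict)


# ---------------------------------------------------------------------------
# R2eff from intensities
# ---------------------------------------------------------------------------

def compute_r2eff(i_cpmg, i0, t_cpmg, i_cpmg_sd=None, i0_sd=None):
    """R2eff = -(1/T_cpmg) ln(I_cpmg / I0), with optional error propagation.

    Returns R2eff (s^-1) or, when intensity uncertainties are supplied, a
    tuple (R2eff, sd). Non-positive intensities raise ValueError: intensity
    sign problems must be handled (flagged) by the caller, never silently
    dropped.
    """
    i_cpmg = np.asarray(i_cpmg, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    if not t_cpmg > 0:
        raise ValueError("t_cpmg must be positive")
    if np.any(i_cpmg <= 0) or np.any(i0 <= 0):
        raise ValueError("intensities must be positive")
    r2 = -np.log(i_cpmg / i0) / t_cpmg
    if i_cpmg_sd is None and i0_sd is None:
        return r2
    i_cpmg_sd = 0.0 if i_cpmg_sd is None else np.asarray(i_cpmg_sd, dtype=float)
    i0_sd = 0.0 if i0_sd is None else np.asarray(i0_sd, dtype=float)
    sd = np.sqrt((i_cpmg_sd / i_cpmg) ** 2 + (i0_sd / i0) ** 2) / t_cpmg
    return r2, sd


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def echo_counts(nu_cpmg, t_cpmg, tol: float = 1e-6) -> np.ndarray:
    """Number of spin echoes n = 2 * nu_cpmg * T_cpmg; must be integer.

    A constant-time CPMG block of length T_cpmg accommodates only pulse
    rates nu = n / (2 T_cpmg) for integer n.
    """
    nu_cpmg = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    n_float = 2.0 * nu_cpmg * t_cpmg
    n = np.round(n_float)
    bad = np.abs(n_float - n) > tol
    if np.any(bad):
        k = np.arange(1, int(np.max(n_float)) + 3)
        allowed = k / (2.0 * t_cpmg)
        raise ValueError(
            f"nu_cpmg values {nu_cpmg[bad]} do not give an integer echo count for "
            f"T_cpmg={t_cpmg}; permissible values are n/(2*T_cpmg), e.g. {allowed[:8]}"
        )
    return n.astype(int)


def _evolution_matrix(kex, p_b, dw_rad, r2):
    """Complex 2x2 free-evolution rate matrix over sites (A, B).

    Offsets are taken in the population-averaged rotating frame:
    Omega_A = -p_b*dw, Omega_B = (1-p_b)*dw, so the averaged line sits at 0.
    """
    p_a = 1.0 - p_b
    k_ab = p_b * kex  # A -> B (forward)
    k_ba = p_a * kex  # B -> A
    omega_a = -p_b * dw_rad
    omega_b = p_a * dw_rad
    return np.array(
        [
            [1j * omega_a - r2 - k_ab, k_ba],
            [k_ab, 1j * omega_b - r2 - k_ba],
        ],
        dtype=complex,
    )


def _propagators(L: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(L * t) for a stack of times; analytic 2x2 eigendecomposition with a
    scipy fallback for (near-)defective matrices."""
    w, v = np.linalg.eig(L)
    try:
        vinv = np.linalg.inv(v)
        cond_ok = np.linalg.cond(v) < 1e10
    except np.linalg.LinAlgError:
        cond_ok = False
    if cond_ok:
        ew = np.exp(np.outer(times, w))  # (m, 2)
        return np.einsum("ij,mj,jk->mik", v, ew, vinv)
    from scipy.linalg import expm

    return np.stack([expm(L * t) for t in times])


def _real4(P: np.ndarray) -> np.ndarray:
    """Real 4x4 representation of a stack of complex 2x2 operators acting on
    magnetization vectors stored as [Re_A, Re_B, Im_A, Im_B]."""
    pr, pi = P.real, P.imag
    top = np.concatenate([pr, -pi], axis=-1)
    bot = np.concatenate([pi, pr], axis=-1)
    return np.concatenate([top, bot], axis=-2)


def _matrix_power_stack(mats: np.ndarray, powers: np.ndarray) -> np.ndarray:
    """Elementwise matrix powers of a stack (m,4,4) with per-matrix exponents."""
    m = mats.shape[0]
    out = np.broadcast_to(np.eye(4), (m, 4, 4)).copy()
    base = mats.copy()
    p = powers.astype(int).copy()
    while np.any(p > 0):
        sel = (p & 1).astype(bool)
        if np.any(sel):
            out[sel] = base[sel] @ out[sel]
        p >>= 1
        if np.any(p > 0):
            base = base @ base
    return out


def simulate_r2eff(kex, p_b, dw_rad, r2_base, nu_cpmg, t_cpmg) -> np.ndarray:
    """R2eff(nu_cpmg) for two-site exchange under an ideal CPMG train.

    The magnetization (complex 2-vector over sites, initialized at the
    equilibrium populations) is evolved through n = 2*nu*T repeats of
    [tau/2 - 180 - tau/2] with tau = 1/(2*nu); the ideal 180 pulse is complex
    conjugation. R2eff = -(1/T) ln |M_A + M_B|(T), since |M(0)| = 1.
    """
    nu_cpmg = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    n = echo_counts(nu_cpmg, t_cpmg)
    L = _evolution_matrix(kex, p_b, dw_rad, r2_base)
    half_tau = 1.0 / (4.0 * nu_cpmg)
    P = _real4(_propagators(L, half_tau))  # (m, 4, 4)
    conj = np.diag([1.0, 1.0, -1.0, -1.0])
    echo = P @ conj @ P
    U = _matrix_power_stack(echo, n)
    m0 = np.array([1.0 - p_b, p_b, 0.0, 0.0])
    m_final = U @ m0
    total = (m_final[:, 0] + m_final[:, 1]) + 1j * (m_final[:, 2] + m_final[:, 3])
    return -np.log(np.abs(total)) / t_cpmg


def dw_rad_per_s(delta_omega_ppm: float, field_mhz: float) -> float:
    """ppm -> rad/s for 15N at the given 1H field."""
    return delta_omega_ppm * field_mhz * GAMMA_RATIO_15N * 2.0 * np.pi


def simulate_profile(model: TwoSiteModel, residue_id: str, field: float,
                     nu_grid, t_cpmg: float) -> np.ndarray:
    """Forward-model R2eff profile for one residue at one static field."""
    dw = dw_rad_per_s(model.delta_omega[residue_id], field)
    r2 = model.r2_base[(residue_id, field)]
    return simulate_r2eff(model.kex, model.p_b, dw, r2, nu_grid, t_cpmg)


def luz_meiboom_rex(kex, p_b, dw_rad, nu_cpmg) -> np.ndarray:
    """Fast-exchange closed form for the exchange contribution:

    Rex(nu) = (p_a p_b dw^2 / kex) * [1 - (4 nu / kex) tanh(kex / (4 nu))]
    """
    nu_cpmg = np.asarray(nu_cpmg, dtype=float)
    x = 4.0 * nu_cpmg / kex
    return (1.0 - p_b) * p_b * dw_rad**2 / kex * (1.0 - x * np.tanh(1.0 / x))


# ---------------------------------------------------------------------------
# Residue selection and fitting
# ---------------------------------------------------------------------------

def group_by_residue(dataset: list[DispersionSeries]) -> dict[str, dict[float, DispersionSeries]]:
    out: dict[str, dict[float, DispersionSeries]] = {}
    for s in dataset:
        out.setdefault(s.residue_id, {})[s.field] = s
    return out


def select_residues(dataset: list[DispersionSeries], span_min: float = 1.0):
    """Keep residues whose dispersion magnitude max-min exceeds *span_min* at
    BOTH fields; residues observed at a single field are excluded.

    Returns (included_ids, excluded: dict id -> reason, spans: dict id -> {field: span}).
    """
    grouped = group_by_residue(dataset)
    included, excluded, spans = [], {}, {}
    for rid, by_field in grouped.items():
        spans[rid] = {f: s.good().span for f, s in by_field.items()}
        if len(by_field) < 2:
            excluded[rid] = f"single field ({list(by_field)})"
            continue
        weak = {f: sp for f, sp in spans[rid].items() if sp <= span_min}
        if weak:
            excluded[rid] = (
                f"dispersion span <= {span_min} s^-1 at field(s) "
                + ", ".join(f"{f:g} MHz ({sp:.3g})" for f, sp in weak.items())
            )
        else:
            included.append(rid)
    return included, excluded, spans


def _model_from_vector(x, residue_ids, fields, fix_kf=None, fix_kb=None):
    """Unpack the optimizer vector into a TwoSiteModel.

    Layout: [kex, p_b?, dw_1..dw_R, r2_{r1,f1}, r2_{r1,f2}, ...]; when the
    forward (back) rate is fixed p_b is derived from kex instead of fitted.
    """
    kex = x[0]
    i = 1
    if fix_kf is not None:
        p_b = min(fix_kf / kex, 0.4999)
    elif fix_kb is not None:
        p_b = min(max(1.0 - fix_kb / kex, 1e-9), 0.4999)
    else:
        p_b = x[1]
        i = 2
    n_res = len(residue_ids)
    dw = dict(zip(residue_ids, x[i:i + n_res]))
    i += n_res
    r2 = {}
    for rid in residue_ids:
        for f in fields:
            r2[(rid, f)] = x[i]
            i += 1
    return TwoSiteModel(kex=kex, p_b=p_b, delta_omega=dw, r2_base=r2)


def _residuals(x, residue_ids, fields, data, t_cpmg, fix_kf, fix_kb):
    model = _model_from_vector(x, residue_ids, fields, fix_kf, fix_kb)
    res = []
    for rid in residue_ids:
        for f in fields:
            s = data[rid][f]
            sim = simulate_profile(model, rid, f, s.nu_cpmg, t_cpmg)
            res.append((sim - s.r2eff) / s.err)
    return np.concatenate(res)


def _initial_dw_ppm(series_by_field: dict[float, DispersionSeries], kex0, p_b0) -> float:
    """Heuristic starting |dw|: invert the fast-limit amplitude at the lower field."""
    f = min(series_by_field)
    s = series_by_field[f].good()
    span = max(s.span, 0.1)
    dw_rad = np.sqrt(span * kex0 / ((1.0 - p_b0) * p_b0))
    return float(dw_rad / (f * GAMMA_RATIO_15N * 2.0 * np.pi))


def _fit(data, residue_ids, fields, t_cpmg, kex0, p_b0, fix_kf, fix_kb):
    x0 = [kex0]
    lo, hi = [1.0], [1e6]
    if fix_kf is None and fix_kb is None:
        x0.append(p_b0)
        lo.append(1e-6)
        hi.append(0.4999)
    for rid in residue_ids:
        x0.append(_initial_dw_ppm(data[rid], kex0, p_b0))
        lo.append(0.0)
        hi.append(60.0)
    for rid in residue_ids:
        for f in fields:
            r = data[rid][f].good()
            x0.append(max(float(np.min(r.r2eff)), 0.5))
            lo.append(0.01)
            hi.append(500.0)
    if fix_kf is not None:
        lo[0] = max(lo[0], 2.0 * fix_kf + 1e-9)  # keep p_b < 0.5
    sol = least_squares(
        _residuals, x0, bounds=(lo, hi),
        args=(residue_ids, fields, data, t_cpmg, fix_kf, fix_kb),
        ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=4000,
    )
    return sol


def _fit_with_multistart(data, residue_ids, fields, t_cpmg,
                         kex_starts=(100.0, 300.0, 1000.0, 3000.0),
                         p_b0=0.05, fix_kf=None, fix_kb=None):
    best = None
    for kex0 in kex_starts:
        if fix_kf is not None and kex0 <= 2.0 * fix_kf:
            kex0 = 2.5 * fix_kf
        if fix_kb is not None and kex0 <= fix_kb:
            kex0 = 1.5 * fix_kb
        sol = _fit(data, residue_ids, fields, t_cpmg, kex0, p_b0, fix_kf, fix_kb)
        if best is None or sol.cost < best.cost:
            best = sol
    return best


def _result_from_solution(sol, residue_ids, fields, data, fix_kf, fix_kb) -> FitResult:
    model = _model_from_vector(sol.x, residue_ids, fields, fix_kf, fix_kb)
    chi2 = float(2.0 * sol.cost)
    n_data = sum(len(data[rid][f].nu_cpmg) for rid in residue_ids for f in fields)
    n_params = len(sol.x)
    param_sd = {}
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.pinv(jtj)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        param_sd["kex"] = float(sds[0])
        if fix_kf is None and fix_kb is None:
            param_sd["p_b"] = float(sds[1])
            off = 2
        else:
            off = 1
        for k, rid in enumerate(residue_ids):
            param_sd[f"dw:{rid}"] = float(sds[off + k])
    except np.linalg.LinAlgError:  # pragma: no cover - singular jacobian
        pass
    return FitResult(model=model, chi2=chi2, n_data=n_data, n_params=n_params,
                     param_sd=param_sd, converged=bool(sol.status > 0))


def fit_single_residue(series_by_field: dict[float, DispersionSeries],
                       t_cpmg: float = 0.040,
                       kex_starts=(100.0, 300.0, 1000.0, 3000.0)) -> FitResult:
    """Two-site fit of one residue (both fields): kex, p_b, |dw|, per-field R2.

    In the fast-exchange limit only the product p_a*p_b*dw^2 is identifiable
    at a single field; a large relative kex uncertainty flags an
    unidentifiable (flat) profile.
    """
    rid = next(iter(series_by_field.values())).residue_id
    data = {rid: {f: s.good() for f, s in series_by_field.items()}}
    fields = sorted(series_by_field)
    sol = _fit_with_multistart(data, [rid], fields, t_cpmg, kex_starts=kex_starts)
    result = _result_from_solution(sol, [rid], fields, data, None, None)
    sd_kex = result.param_sd.get("kex", np.inf)
    if not result.converged or sd_kex > 10.0 * result.model.kex:
        result.converged = False
        result.excluded_residues[rid] = "unidentifiable or non-convergent single-residue fit"
    return result


def papb_dw2(model: TwoSiteModel, residue_id: str) -> float:
    """p_a * p_b * dw^2 in ppm^2 units (field-independent amplitude)."""
    return (1.0 - model.p_b) * model.p_b * model.delta_omega[residue_id] ** 2


def fit_global(dataset: list[DispersionSeries], t_cpmg: float = 0.040,
               span_min: float = 1.0, exclude_reduced_chi2: float | None = 3.0,
               fix_kf: float | None = None, fix_kb: float | None = None,
               kex_starts=(100.0, 300.0, 1000.0, 3000.0)) -> FitResult:
    """Global two-site fit: shared kex and p_b across residues and fields.

    Residues failing the dispersion-span selection are excluded up front;
    residues whose individual fits have reduced chi-square above
    *exclude_reduced_chi2* are excluded before the final shared fit (set to
    None to skip the pre-screen). Consistency re-fits with a fixed forward
    rate (fix_kf = p_b*kex) or back rate (fix_kb) are supported.
    """
    if fix_kf is not None and fix_kb is not None:
        raise ValueError("fix at most one of the forward and back rates")
    included, excluded, _ = select_residues(dataset, span_min=span_min)
    grouped = group_by_residue(dataset)
    data = {rid: {f: s.good() for f, s in grouped[rid].items()} for rid in included}

    if exclude_reduced_chi2 is not None:
        for rid in list(included):
            single = fit_single_residue(data[rid], t_cpmg, kex_starts=kex_starts)
            if single.reduced_chi2 > exclude_reduced_chi2:
                excluded[rid] = (
                    f"individual reduced chi2 {single.reduced_chi2:.2f} > "
                    f"{exclude_reduced_chi2}"
                )
                included.remove(rid)

    if len(included) < 2:
        raise ValueError(f"need >=2 included residues for a global fit; excluded: {excluded}")
    fields = sorted({f for rid in included for f in data[rid]})
    if len(fields) < 2:
        raise ValueError("global fit requires data at two static fields")
    n_data = sum(len(data[rid][f].nu_cpmg) for rid in included for f in fields)
    n_params = 2 + len(included) + len(included) * len(fields)
    if fix_kf is not None or fix_kb is not None:
        n_params -= 1
    if n_params >= n_data:
        raise ValueError(f"under-determined: {n_params} parameters for {n_data} points")

    sol = _fit_with_multistart(data, included, fields, t_cpmg,
                               kex_starts=kex_starts, fix_kf=fix_kf, fix_kb=fix_kb)
    result = _result_from_solution(sol, included, fields, data, fix_kf, fix_kb)
    result.excluded_residues = excluded
    return result


def profile_forward_rate(dataset: list[DispersionSeries], kf_grid,
                         t_cpmg: float = 0.040, span_min: float = 1.0,
                         exclude_reduced_chi2: float | None = 3.0):
    """chi-square profile over a fixed forward rate k_f = p_b * kex.

    For each k_f on the grid all remaining parameters are refitted. Returns
    (kf_best, chi2_curve as list of (kf, chi2), delta-chi2=1 interval).
    """
    kf_grid = np.asarray(kf_grid, dtype=float)
    curve = []
    for kf in kf_grid:
        fit = fit_global(dataset, t_cpmg=t_cpmg, span_min=span_min,
                         exclude_reduced_chi2=exclude_reduced_chi2, fix_kf=float(kf))
        curve.append((float(kf), fit.chi2))
    chi2 = np.array([c for _, c in curve])
    i = int(np.argmin(chi2))
    if i == 0 or i == len(kf_grid) - 1:
        warnings.warn("forward-rate grid does not bracket the chi2 minimum")
        kf_best = float(kf_grid[i])
    else:
        # parabolic refinement through the bracketing triple
        x, y = kf_grid[i - 1:i + 2], chi2[i - 1:i + 2]
        denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
        a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
        b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
        kf_best = float(-b / (2 * a)) if a > 0 else float(kf_grid[i])
    # delta-chi2 = 1 interval by linear interpolation on each side of the minimum
    target = chi2.min() + 1.0
    lo, hi = kf_grid[0], kf_grid[-1]
    for j in range(i, 0, -1):
        if chi2[j - 1] >= target:
            lo = np.interp(target, [chi2[j], chi2[j - 1]], [kf_grid[j], kf_grid[j - 1]])
            break
    for j in range(i, len(kf_grid) - 1):
        if chi2[j + 1] >= target:
            hi = np.interp(target, [chi2[j], chi2[j + 1]], [kf_grid[j], kf_grid[j + 1]])
            break
    return kf_best, curve, (float(lo), float(hi))


def compute_alpha(dataset: list[DispersionSeries],
                  r2_base: dict[tuple[str, float], float]) -> AlphaEstimate:
    """Field-dependence exponent of Rex from the two-point estimator

        alpha = [(B2+B1)/(B2-B1)] * [(Rex2-Rex1)/(Rex2+Rex1)]

    with Rex taken as R2eff at the lowest nu_cpmg minus the exchange-free R2.
    alpha -> 2 in fast exchange and -> 0 in slow exchange; the two-point form
    saturates slightly below 2 (1.96 for 600/800 MHz). Residues with
    non-positive Rex at either field are skipped with a reason.
    """
    grouped = group_by_residue(dataset)
    per_residue: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for rid, by_field in grouped.items():
        if len(by_field) < 2:
            skipped[rid] = "requires two fields"
            continue
        f1, f2 = sorted(by_field)[:2]
        rex = {}
        ok = True
        for f in (f1, f2):
            s = by_field[f].good()
            r2eff_min_nu = s.r2eff[np.argmin(s.nu_cpmg)]
            rex[f] = r2eff_min_nu - r2_base[(rid, f)]
            if rex[f] <= 0:
                skipped[rid] = f"Rex <= 0 at {f:g} MHz"
                ok = False
        if not ok:
            continue
        per_residue[rid] = float(
            (f2 + f1) / (f2 - f1) * (rex[f2] - rex[f1]) / (rex[f2] + rex[f1])
        )
    vals = np.array(list(per_residue.values()))
    mean = float(vals.mean()) if len(vals) else np.nan
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return AlphaEstimate(per_residue=per_residue, mean=mean, sd=sd, skipped=skipped)


def correlate_with_binding_shifts(fit: FitResult,
                                  binding_shifts: dict[str, float],
                                  ring_corrections: dict[str, float] | None = None):
    """Conformational-selection check: fitted sqrt(p_a p_b dw^2) (ppm) vs the
    magnitude of the ring-current-corrected free->bound 15N shift change.

    If the excited state of the free protein is the bound-like closed
    conformation, the fitted sqrt(p_a p_b) * |dw| should be proportional to
    the binding shift change with slope s = sqrt(p_a p_b). Returns a dict
    with slope, r_squared, p_a_p_b = s^2, p_b (smaller root of p(1-p)=s^2),
    and k_f = p_b * kex.
    """
    ring_corrections = ring_corrections or {}
    common = sorted(set(fit.model.delta_omega) & set(binding_shifts))
    if len(common) < 3:
        raise ValueError(f"need >=3 residues common to fit and shift table, got {len(common)}")
    x = np.array([abs(binding_shifts[r] - ring_corrections.get(r, 0.0)) for r in common])
    y = np.array([np.sqrt(papb_dw2(fit.model, r)) for r in common])
    slope = float(x @ y / (x @ x))  # through-origin least squares
    nonphysical = slope < 0
    r = np.corrcoef(x, y)[0, 1] if len(common) > 2 else np.nan
    s2 = slope**2
    if s2 > 0.25:
        p_b = 0.5  # saturated: populations indistinguishable
    else:
        p_b = (1.0 - np.sqrt(1.0 - 4.0 * s2)) / 2.0
    return {
        "residues": common,
        "slope": slope,
        "r_squared": float(r**2),
        "p_a_p_b": s2,
        "p_b": float(p_b),
        "k_f": float(p_b * fit.model.kex),
        "nonphysical": bool(nonphysical),
    }


def rates_from_populations(kex: float, p_b: float) -> tuple[float, float]:
    """(k_forward, k_back) from kex = k_forward + k_back and p_b."""
    if not kex > 0 or not 0 <= p_b < 0.5:
        raise ValueError("require kex > 0 and 0 <= p_b < 0.5")
    return p_b * kex, (1.0 - p_b) * kex


def population_from_rates(kex: float, k_forward: float) -> float:
    """Minor population p_b = k_forward / kex."""
    if k_forward > kex:
        raise ValueError("k_forward cannot exceed kex")
    if not kex > 0 or k_forward < 0:
        raise ValueError("require kex > 0 and k_forward >= 0")
    return k_forward / kex
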