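"""Two-state CPMG relaxation-dispersion: forward models and global fitting.

A spin exchanging between a major conformer B and a minor conformer E
(populations ``1-p_minor`` and ``p_minor``, exchange rate
``kex = k_BE + k_EB``) shows an effective transverse relaxation rate
R2,eff that depends on the refocusing frequency ν_CPMG of a
constant-time CPMG element.  The forward model propagates transverse
single-quantum magnetization through the Bloch–McConnell evolution
matrix; the Carver–Richards closed form is provided as an independent
analytical route.  Global fitting ties all residues (and fields) at one
temperature to a single (kex, p_minor) pair with per-residue Δω and
per-profile R2,0.

Echo convention: one CPMG element is δ–π–2δ–π–δ with δ = 1/(4 ν_CPMG),
so T_CPMG·ν_CPMG must be a positive integer (one element at the minimum
frequency 1/T_CPMG).  π pulses are ideal and act as complex conjugation
of the transverse magnetization; only in-phase magnetization is
propagated.  The sign of Δω is not identifiable from CPMG data alone,
so fits constrain Δω ≥ 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.linalg import matrix_power
from scipy.optimize import least_squares

from .constants import dw_ppm_to_rad_s

__all__ = [
    "DispersionProfile",
    "DispersionDataset",
    "TwoStateFit",
    "r2eff_from_intensities",
    "simulate_r2eff_bm",
    "carver_richards_r2eff",
    "fit_two_state_global",
    "bootstrap_errors",
]

_NU_COMMENSURATE_RTOL = 1e-6


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DispersionProfile:
    """One residue's R2,eff(ν_CPMG) curve at fixed field and temperature."""

    residue: str
    nucleus: str
    field_t: float
    temperature_k: float
    t_cpmg: float
    nu_cpmg: np.ndarray
    r2eff: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.nu_cpmg = np.asarray(self.nu_cpmg, dtype=float)
        self.r2eff = np.asarray(self.r2eff, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.nu_cpmg.ndim != 1 or len(self.nu_cpmg) == 0:
            raise ValueError("profile needs at least one dispersion point")
        if len({len(self.nu_cpmg), len(self.r2eff), len(self.sigma)}) != 1:
            raise ValueError("nu_cpmg, r2eff and sigma must have equal length")
        if np.any(self.nu_cpmg <= 0):
            raise ValueError("nu_cpmg values must be positive")
        if len(np.unique(self.nu_cpmg)) != len(self.nu_cpmg):
            raise ValueError("nu_cpmg values must be unique within a profile")
        if self.t_cpmg <= 0:
            raise ValueError("t_cpmg must be positive")
        if np.any(self.nu_cpmg < 1.0 / self.t_cpmg * (1 - 1e-9)):
            raise ValueError("nu_cpmg below the minimum 1/T_CPMG")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")

    @property
    def key(self) -> tuple:
        return (self.residue, self.nucleus, self.field_t, self.temperature_k)

    def __len__(self) -> int:
        return len(self.nu_cpmg)


@dataclass
class DispersionDataset:
    """A collection of dispersion profiles fitted together.

    ``truth`` optionally carries the generating parameters of a synthetic
    dataset so recovery tests can compare against ground truth.
    """

    profiles: list[DispersionProfile]
    truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("dataset needs at least one profile")

    @property
    def residues(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.profiles:
            seen.setdefault(p.residue)
        return list(seen)

    @property
    def n_points(self) -> int:
        return sum(len(p) for p in self.profiles)

    def to_frame(self):
        import pandas as pd

        rows = []
        for p in self.profiles:
            for nu, r2, sg in zip(p.nu_cpmg, p.r2eff, p.sigma):
                rows.append(
                    dict(
                        residue=p.residue,
                        nucleus=p.nucleus,
                        field_T=p.field_t,
                        temp_K=p.temperature_k,
                        t_cpmg_s=p.t_cpmg,
                        nu_cpmg_hz=nu,
                        r2eff_s1=r2,
                        sigma_s1=sg,
                    )
                )
        return pd.DataFrame(rows)


@dataclass
class TwoStateFit:
    """Result of a global two-state dispersion fit."""

    kex: float
    p_minor: float
    dw_ppm: dict[str, float]
    r2_0: dict[tuple, float]
    chi2: float
    redchi: float
    n_data: int
    n_params: int
    success: bool
    unidentifiable: bool = False
    message: str = ""
    errors: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.success and not np.isfinite(self.chi2):
            raise ValueError("converged fit must have finite chi2")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def r2eff_from_intensities(intensity: float, reference: float, t_cpmg: float) -> float:
    """R2,eff = −ln(I/I0)/T_CPMG from peak intensities with and without
    the relaxation delay."""
    intensity = np.asarray(intensity, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(intensity <= 0) or np.any(reference <= 0):
        raise ValueError("intensities must be positive to take the logarithm")
    if t_cpmg <= 0:
        raise ValueError("t_cpmg must be positive")
    out = -np.log(intensity / reference) / t_cpmg
    return float(out) if out.ndim == 0 else out


def _n_echo_elements(nu: np.ndarray, t_cpmg: float) -> np.ndarray:
    """Number of δ–π–2δ–π–δ elements; rejects incommensurate ν/T pairs."""
    n_float = np.asarray(nu, dtype=float) * t_cpmg
    n = np.rint(n_float)
    bad = (n < 1) | (np.abs(n_float - n) > _NU_COMMENSURATE_RTOL * np.maximum(n_float, 1.0))
    if np.any(bad):
        raise ValueError(
            f"nu_cpmg values {np.asarray(nu)[bad]} are not commensurate with "
            f"T_CPMG={t_cpmg}: T_CPMG*nu must be a positive integer"
        )
    return n.astype(int)


def simulate_r2eff_bm(
    nu_cpmg,
    *,
    kex: float,
    p_minor: float,
    dw_rad_s: float,
    r2_0: float,
    t_cpmg: float,
):
    """Numerical Bloch–McConnell R2,eff for two-state exchange.

    The transverse magnetization vector (M_B, M_E) evolves under
    ``dM/dt = L M`` with ``L = K - R2,0·I - i·diag(0, Δω)`` where K is
    the two-state exchange generator.  Ideal π pulses conjugate M, so a
    full echo element δ–π–2δ–π–δ acts as the matrix
    ``P1 · conj(P2) · P1`` with ``P1 = expm(L δ)`` and ``P2 = P1²``.
    Starting from equilibrium populations, the observed intensity is the
    magnitude of the major-state component and
    ``R2,eff = −ln(|M_B(T)| / (1−p_minor)) / T``.

    Parameters use the minor-state convention: ``k_BE = p_minor·kex``
    (major→minor) and ``k_EB = (1−p_minor)·kex``.  ``dw_rad_s`` is the
    chemical-shift difference in rad s^-1.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    if kex < 0:
        raise ValueError("kex must be non-negative")
    if not 0 <= p_minor < 1:
        raise ValueError("p_minor must lie in [0, 1)")
    if r2_0 < 0:
        raise ValueError("r2_0 must be non-negative")
    n_elem = _n_echo_elements(nu, t_cpmg)

    k_be = p_minor * kex
    k_eb = (1.0 - p_minor) * kex
    ell = np.array(
        [
            [-r2_0 - k_be, k_eb],
            [k_be, -r2_0 - k_eb - 1j * dw_rad_s],
        ],
        dtype=complex,
    )
    m0 = np.array([1.0 - p_minor, p_minor], dtype=complex)

    # closed-form expm of the 2x2 evolution matrix, batched over δ = 1/(4ν):
    # expm(Lδ) = e^{μ+δ}(L−μ−I)/(μ+−μ−) + e^{μ−δ}(L−μ+I)/(μ−−μ+)
    tr = ell[0, 0] + ell[1, 1]
    disc = np.sqrt(tr * tr / 4.0 - (ell[0, 0] * ell[1, 1] - ell[0, 1] * ell[1, 0]))
    mu_p = tr / 2.0 + disc
    mu_m = tr / 2.0 - disc
    eye = np.eye(2, dtype=complex)
    delta = 1.0 / (4.0 * nu)
    if abs(mu_p - mu_m) < 1e-12 * max(1.0, abs(mu_p)):
        # degenerate eigenvalues: expm(Lδ) = e^{μδ}(I + (L−μI)δ)
        p1 = np.exp(mu_p * delta)[:, None, None] * (
            eye[None, :, :] + (ell - mu_p * eye)[None, :, :] * delta[:, None, None]
        )
    else:
        a_p = (ell - mu_m * eye) / (mu_p - mu_m)
        a_m = (ell - mu_p * eye) / (mu_m - mu_p)
        p1 = (
            np.exp(mu_p * delta)[:, None, None] * a_p[None, :, :]
            + np.exp(mu_m * delta)[:, None, None] * a_m[None, :, :]
        )
    element = p1 @ np.conj(p1 @ p1) @ p1

    out = np.empty(len(nu))
    for j in range(len(nu)):
        m_t = matrix_power(element[j], int(n_elem[j])) @ m0
        out[j] = -np.log(np.abs(m_t[0]) / (1.0 - p_minor)) / t_cpmg
    return out if np.ndim(nu_cpmg) else float(out[0])


def carver_richards_r2eff(
    nu_cpmg,
    *,
    kex: float,
    p_minor: float,
    dw_rad_s: float,
    r2_0: float,
):
    """Carver–Richards analytical R2,eff for two-state exchange.

    Closed form for equal intrinsic rates in both states.  Degenerate
    arguments outside the real arccosh domain are handled by evaluating
    the arccosh on the complex plane and taking the real part.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg, dtype=float))
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    if kex < 0 or not 0 <= p_minor < 1:
        raise ValueError("invalid exchange parameters")
    if dw_rad_s == 0 or p_minor == 0 or kex == 0:
        out = np.full(len(nu), float(r2_0))
        return out if np.ndim(nu_cpmg) else float(out[0])

    p_major = 1.0 - p_minor
    dw = dw_rad_s
    psi = kex**2 - dw**2
    zeta = -2.0 * dw * kex * (p_major - p_minor)
    root = np.sqrt(psi**2 + zeta**2)
    d_plus = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root)
    d_minus = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root)
    eta_plus = np.sqrt(np.maximum(psi + root, 0.0) / 2.0) / (2.0 * nu)
    eta_minus = np.sqrt(np.maximum(-psi + root, 0.0) / 2.0) / (2.0 * nu)
    arg = d_plus * np.cosh(eta_plus) - d_minus * np.cos(eta_minus)
    out = r2_0 + 0.5 * kex - nu * np.real(np.arccosh(arg.astype(complex)))
    return out if np.ndim(nu_cpmg) else float(out[0])


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

#: Documented multi-start grid (kex in s^-1, p_minor fraction).
INIT_GRID_KEX = (500.0, 2000.0, 8000.0)
INIT_GRID_PMINOR = (0.01, 0.05, 0.2)

_DEFAULT_BOUNDS = {
    "kex": (1.0, 1e6),
    "p_minor": (1e-4, 0.5),
    "dw_ppm": (0.0, 50.0),
    "r2_0": (0.0, 1e3),
}


def _pack(kex, p_minor, dw_by_res, r2_by_prof, residues, keys):
    return np.concatenate(
        [[kex, p_minor], [dw_by_res[r] for r in residues], [r2_by_prof[k] for k in keys]]
    )


def _unpack(theta, residues, keys):
    kex, p_minor = theta[0], theta[1]
    dw = dict(zip(residues, theta[2 : 2 + len(residues)]))
    r2 = dict(zip(keys, theta[2 + len(residues) :]))
    return kex, p_minor, dw, r2


def _residuals(theta, dataset, residues, keys):
    kex, p_minor, dw, r2 = _unpack(theta, residues, keys)
    res = []
    for prof in dataset.profiles:
        dw_rad = dw_ppm_to_rad_s(dw[prof.residue], prof.nucleus, prof.field_t)
        model = simulate_r2eff_bm(
            prof.nu_cpmg,
            kex=kex,
            p_minor=p_minor,
            dw_rad_s=dw_rad,
            r2_0=r2[prof.key],
            t_cpmg=prof.t_cpmg,
        )
        res.append((prof.r2eff - model) / prof.sigma)
    return np.concatenate(res)


def _data_amplitude(dataset: DispersionDataset) -> float:
    return max(float(np.ptp(p.r2eff)) for p in dataset.profiles)


def fit_two_state_global(
    dataset: DispersionDataset,
    init: dict | TwoStateFit | None = None,
    bounds: dict | None = None,
    multi_start: bool = True,
) -> TwoStateFit:
    """Globally fit (kex, p_minor) plus per-residue Δω and per-profile R2,0.

    Minimizes Σ((R2,eff_obs − R2,eff_model)/σ)² with a trust-region
    least-squares solver.  By default a multi-start over the documented
    (kex, p_minor) grid is run and the lowest-χ² solution kept; an
    explicit ``init`` is prepended to the start list.  A dataset whose
    dispersion amplitude is indistinguishable from zero (p_minor·Δω² ≈ 0)
    is flagged ``unidentifiable`` rather than silently returned.
    """
    if any(np.any(p.sigma <= 0) for p in dataset.profiles):
        raise ValueError("all sigma must be positive for weighted fitting")
    residues = dataset.residues
    keys = [p.key for p in dataset.profiles]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate profile keys in dataset")
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    r2_init = {p.key: float(np.min(p.r2eff)) for p in dataset.profiles}
    dw_init = {r: 2.0 for r in residues}

    starts: list[np.ndarray] = []
    if init is not None:
        if isinstance(init, TwoStateFit):
            starts.append(_pack(init.kex, init.p_minor, init.dw_ppm, init.r2_0, residues, keys))
        else:
            starts.append(
                _pack(
                    init.get("kex", 2000.0),
                    init.get("p_minor", 0.05),
                    init.get("dw_ppm", dw_init) if isinstance(init.get("dw_ppm"), dict) else dw_init,
                    init.get("r2_0", r2_init) if isinstance(init.get("r2_0"), dict) else r2_init,
                    residues,
                    keys,
                )
            )
    if multi_start or not starts:
        for kx in INIT_GRID_KEX:
            for pm in INIT_GRID_PMINOR:
                starts.append(_pack(kx, pm, dw_init, r2_init, residues, keys))
        if not multi_start and init is None:
            starts = starts[:1]

    lo = np.concatenate(
        [[b["kex"][0], b["p_minor"][0]], [b["dw_ppm"][0]] * len(residues), [b["r2_0"][0]] * len(keys)]
    )
    hi = np.concatenate(
        [[b["kex"][1], b["p_minor"][1]], [b["dw_ppm"][1]] * len(residues), [b["r2_0"][1]] * len(keys)]
    )

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        sol = least_squares(
            _residuals,
            theta0,
            bounds=(lo, hi),
            args=(dataset, residues, keys),
            method="trf",
            x_scale="jac",
        )
        if best is None or sol.cost < best.cost:
            best = sol

    kex, p_minor, dw, r2 = _unpack(best.x, residues, keys)
    chi2 = float(2.0 * best.cost)
    n_data = dataset.n_points
    n_params = len(best.x)
    dof = max(n_data - n_params, 1)

    # degeneracy check: exchange contribution indistinguishable from zero
    amp_model = p_minor * max(dw.values(), default=0.0) ** 2
    unident = _data_amplitude(dataset) < 1e-9 or amp_model < 1e-12

    return TwoStateFit(
        kex=float(kex),
        p_minor=float(p_minor),
        dw_ppm={r: float(v) for r, v in dw.items()},
        r2_0={k: float(v) for k, v in r2.items()},
        chi2=chi2,
        redchi=chi2 / dof,
        n_data=n_data,
        n_params=n_params,
        success=bool(best.success),
        unidentifiable=bool(unident),
        message=str(best.message),
    )


def bootstrap_errors(
    dataset: DispersionDataset,
    fit: TwoStateFit,
    n_boot: int = 100,
    seed: int = 0,
) -> dict:
    """Residual-resampling bootstrap uncertainties for a converged fit.

    Standardized residuals are pooled across all points, resampled with
    replacement, rescaled by each point's σ and added back onto the
    fitted model; every replicate is refit starting from the converged
    parameters.  Returns per-parameter standard deviations and
    2.5/16/50/84/97.5% quantiles.
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    if not fit.success:
        raise ValueError("bootstrap requires a converged fit")
    rng = np.random.default_rng(seed)

    models = []
    pooled = []
    for prof in dataset.profiles:
        dw_rad = dw_ppm_to_rad_s(fit.dw_ppm[prof.residue], prof.nucleus, prof.field_t)
        model = simulate_r2eff_bm(
            prof.nu_cpmg,
            kex=fit.kex,
            p_minor=fit.p_minor,
            dw_rad_s=dw_rad,
            r2_0=fit.r2_0[prof.key],
            t_cpmg=prof.t_cpmg,
        )
        models.append(model)
        pooled.append((prof.r2eff - model) / prof.sigma)
    pooled = np.concatenate(pooled)
    # fitted residuals underestimate the noise scale; standard dof correction
    dof = max(len(pooled) - fit.n_params, 1)
    pooled = pooled * np.sqrt(len(pooled) / dof)

    samples: dict[str, list[float]] = {"kex": [], "p_minor": []}
    for r in fit.dw_ppm:
        samples[f"dw_ppm:{r}"] = []
    for b_i in range(n_boot):
        e_star = rng.choice(pooled, size=len(pooled), replace=True)
        offset = 0
        profs = []
        for prof, model in zip(dataset.profiles, models):
            n = len(prof)
            y_star = model + prof.sigma * e_star[offset : offset + n]
            offset += n
            profs.append(
                DispersionProfile(
                    residue=prof.residue,
                    nucleus=prof.nucleus,
                    field_t=prof.field_t,
                    temperature_k=prof.temperature_k,
                    t_cpmg=prof.t_cpmg,
                    nu_cpmg=prof.nu_cpmg,
                    r2eff=y_star,
                    sigma=prof.sigma,
                )
            )
        boot_fit = fit_two_state_global(
            DispersionDataset(profs), init=fit, multi_start=False
        )
        samples["kex"].append(boot_fit.kex)
        samples["p_minor"].append(boot_fit.p_minor)
        for r, v in boot_fit.dw_ppm.items():
            samples[f"dw_ppm:{r}"].append(v)

    q_levels = [2.5, 16.0, 50.0, 84.0, 97.5]
    summary = {}
    for name, vals in samples.items():
        arr = np.asarray(vals)
        summary[name] = {
            "std": float(np.std(arr, ddof=1)),
            "quantiles": {str(q): float(np.percentile(arr, q)) for q in q_levels},
        }
    return {"n_boot": n_boot, "seed": seed, "parameters": summary}
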