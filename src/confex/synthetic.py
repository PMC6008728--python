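"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the raw data of a conformational-exchange
study without requiring spectrometers or MD engines:

* CPMG dispersion datasets — the Bloch–McConnell forward model plus
  homoscedastic Gaussian noise on R2,eff (per-point σ override via the
  stored sigma column);
* discrete-state Markov-chain trajectories from an explicit rate or
  transition matrix, standing in for microstate-annotated MD;
* overdamped Langevin (Euler–Maruyama) trajectories on constructed 2-D
  potentials built from Gaussian wells plus a harmonic confinement —
  a continuous stand-in for MD on a rugged free-energy surface with two
  major minima (E, B) and optional intermediate traps.

Every generator is a pure function of its specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit
from scipy.linalg import expm

from . import cpmg as _cpmg
from .constants import dw_ppm_to_rad_s
from .msm import FeatureTraj, StateTraj

__all__ = [
    "ExchangeTruth",
    "PotentialSpec",
    "GeneratorMatrixSpec",
    "UnstableIntegrationError",
    "gen_cpmg_dataset",
    "gen_markov_traj",
    "gen_langevin_traj",
    "default_rugged_potential",
    "double_well_potential",
    "default_19state_generator",
    "DEFAULT_R2EFF_NOISE_SD",
]

#: Default Gaussian noise on synthetic R2,eff values, s^-1.  Chosen as a
#: realistic repeat-measurement error for well-resolved amide dispersion
#: data; no canonical value exists, so this is an explicit fixture choice.
DEFAULT_R2EFF_NOISE_SD = 0.3


# ---------------------------------------------------------------------------
# CPMG dispersion
# ---------------------------------------------------------------------------

@dataclass
class ExchangeTruth:
    """Ground-truth two-state exchange parameters for a synthetic dataset.

    ``p_e`` follows the minor-state convention (0 < p_e < 0.5);
    ``dw_ppm`` maps residue ids to chemical-shift differences and
    ``r2_0`` maps spectrometer field (T) to the intrinsic rate."""

    kex: float
    p_e: float
    dw_ppm: dict[str, float]
    r2_0: dict[float, float]
    nucleus: str = "15N"
    fields: tuple[float, ...] = (11.7,)
    temperature_k: float = 298.15

    def __post_init__(self) -> None:
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if not 0 < self.p_e < 0.5:
            raise ValueError("p_e must lie in (0, 0.5) (minor-state convention)")
        if isinstance(self.r2_0, (int, float)):
            self.r2_0 = {f: float(self.r2_0) for f in self.fields}
        if any(v < 0 for v in self.r2_0.values()):
            raise ValueError("r2_0 must be non-negative")
        missing = [f for f in self.fields if f not in self.r2_0]
        if missing:
            raise ValueError(f"r2_0 missing for fields {missing}")

    def as_dict(self) -> dict:
        return dict(
            kex=self.kex,
            p_e=self.p_e,
            dw_ppm=dict(self.dw_ppm),
            r2_0={str(k): v for k, v in self.r2_0.items()},
            nucleus=self.nucleus,
            fields=list(self.fields),
            temperature_k=self.temperature_k,
        )


def gen_cpmg_dataset(
    truth: ExchangeTruth,
    nu_list,
    t_cpmg: float,
    noise_sd: float = DEFAULT_R2EFF_NOISE_SD,
    seed: int = 0,
) -> _cpmg.DispersionDataset:
    """Synthetic dispersion dataset: forward model + Gaussian noise.

    One profile per residue per field; R2,eff = Bloch–McConnell model
    + N(0, noise_sd).  The stored σ column equals ``noise_sd`` (or a
    unit placeholder for noiseless data so weighted fits stay defined).
    The generating parameters are attached as ``dataset.truth``.
    """
    nu = np.asarray(nu_list, dtype=float)
    if nu.size == 0:
        raise ValueError("nu_list must not be empty")
    if np.any(nu < (1.0 / t_cpmg) * (1 - 1e-9)):
        raise ValueError("nu_cpmg below the minimum possible value 1/T_CPMG")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = noise_sd if noise_sd > 0 else 1.0
    profiles = []
    for residue, dw_ppm in truth.dw_ppm.items():
        for field_t in truth.fields:
            dw_rad = dw_ppm_to_rad_s(dw_ppm, truth.nucleus, field_t)
            model = _cpmg.simulate_r2eff_bm(
                nu,
                kex=truth.kex,
                p_minor=truth.p_e,
                dw_rad_s=dw_rad,
                r2_0=truth.r2_0[field_t],
                t_cpmg=t_cpmg,
            )
            r2eff = model + rng.normal(0.0, noise_sd, size=len(nu)) if noise_sd > 0 else model
            profiles.append(
                _cpmg.DispersionProfile(
                    residue=residue,
                    nucleus=truth.nucleus,
                    field_t=field_t,
                    temperature_k=truth.temperature_k,
                    t_cpmg=t_cpmg,
                    nu_cpmg=nu,
                    r2eff=np.asarray(r2eff, dtype=float),
                    sigma=np.full(len(nu), float(sigma)),
                )
            )
    return _cpmg.DispersionDataset(profiles, truth=truth.as_dict())


# ---------------------------------------------------------------------------
# discrete-state Markov chains
# ---------------------------------------------------------------------------

@dataclass
class GeneratorMatrixSpec:
    """Exact generator of a discrete-state Markov process.

    Either a rate matrix ``rate_matrix`` (s^-1, rows sum to zero) or a
    row-stochastic ``t_gen`` with time step ``dt``.  When a rate matrix
    is given, ``t_gen = expm(K·dt)``."""

    n_states: int
    dt: float
    rate_matrix: np.ndarray | None = None
    t_gen: np.ndarray | None = None

    def __post_init__(self) -> None:
        if (self.rate_matrix is None) == (self.t_gen is None):
            raise ValueError("provide exactly one of rate_matrix or t_gen")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.rate_matrix is not None:
            k = np.asarray(self.rate_matrix, dtype=float)
            if k.shape != (self.n_states, self.n_states):
                raise ValueError("rate matrix shape mismatch")
            off = k - np.diag(np.diag(k))
            if np.any(off < 0):
                raise ValueError("off-diagonal rates must be non-negative")
            if np.any(np.abs(k.sum(axis=1)) > 1e-12 * max(1.0, np.abs(k).max())):
                raise ValueError("rate matrix rows must sum to zero")
            self.rate_matrix = k
            self.t_gen = expm(k * self.dt)
        else:
            t = np.asarray(self.t_gen, dtype=float)
            if t.shape != (self.n_states, self.n_states):
                raise ValueError("transition matrix shape mismatch")
            if np.any(t < 0) or np.any(np.abs(t.sum(axis=1) - 1.0) > 1e-12):
                raise ValueError("t_gen must be row-stochastic")
            self.t_gen = t

    @property
    def stationary(self) -> np.ndarray:
        lam, vec = np.linalg.eig(self.t_gen.T)
        idx = int(np.argmin(np.abs(lam - 1.0)))
        pi = np.real(vec[:, idx])
        pi = np.abs(pi)
        return pi / pi.sum()

    @property
    def slowest_relaxation_time(self) -> float:
        """−dt/ln λ₂ of the generating transition matrix (time units of dt)."""
        lam = np.sort(np.real(np.linalg.eigvals(self.t_gen)))[::-1]
        return -self.dt / np.log(lam[1])


def gen_markov_traj(
    spec: GeneratorMatrixSpec,
    n_steps: int,
    seed: int = 0,
    start: int | str = 0,
) -> StateTraj:
    """Sample a state trajectory exactly from the generator.

    ``start`` is a state id, or ``"stationary"`` to draw the initial
    state from the generator's stationary distribution."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    if isinstance(start, str):
        if start != "stationary":
            raise ValueError("start must be a state id or 'stationary'")
        s = int(rng.choice(spec.n_states, p=spec.stationary))
    else:
        s = int(start)
        if not 0 <= s < spec.n_states:
            raise ValueError(f"start state {s} outside 0..{spec.n_states - 1}")
    cum = np.cumsum(spec.t_gen, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(n_steps - 1)
    out = np.empty(n_steps, dtype=np.int64)
    out[0] = s
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        out[t] = s
    return StateTraj(out, spec.dt)


# ---------------------------------------------------------------------------
# overdamped Langevin dynamics on constructed potentials
# ---------------------------------------------------------------------------

class UnstableIntegrationError(RuntimeError):
    """Raised when a trajectory escapes the confining region (dt too large)."""


@dataclass
class PotentialSpec:
    """2-D potential: Gaussian wells plus global harmonic confinement.

    U(x) = −Σ_i depth_i·k_BT·exp(−|x−c_i|²/(2 w_i²)) + ½ k_conf |x|².
    Depths are in multiples of k_BT, widths and centers in length units,
    ``diffusion`` in length²/time."""

    wells: list[tuple[tuple[float, float], float, float]]  # (center, depth, width)
    confine_k: float
    kbt: float = 1.0
    diffusion: float = 1.0
    version: int = 1

    def __post_init__(self) -> None:
        if len(self.wells) < 2:
            raise ValueError("need at least two wells")
        for _, depth, width in self.wells:
            if depth <= 0 or width <= 0:
                raise ValueError("well depths and widths must be positive")
        if self.confine_k < 0 or self.kbt <= 0 or self.diffusion <= 0:
            raise ValueError("invalid confinement/thermal/diffusion parameters")

    def _well_arrays(self):
        centers = np.array([c for c, _, _ in self.wells], dtype=float)
        amps = np.array([d * self.kbt for _, d, _ in self.wells], dtype=float)
        widths = np.array([w for _, _, w in self.wells], dtype=float)
        return centers, amps, widths

    def energy(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        centers, amps, widths = self._well_arrays()
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        u = -(amps[None, :] * np.exp(-d2 / (2 * widths[None, :] ** 2))).sum(axis=1)
        u = u + 0.5 * self.confine_k * (x**2).sum(axis=1)
        return u if u.size > 1 else float(u[0])

    def gradient(self, x) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        centers, amps, widths = self._well_arrays()
        diff = x[:, None, :] - centers[None, :, :]
        d2 = (diff**2).sum(axis=2)
        e = amps[None, :] * np.exp(-d2 / (2 * widths[None, :] ** 2))
        g = (e[:, :, None] * diff / widths[None, :, None] ** 2).sum(axis=1)
        g = g + self.confine_k * x
        return g

    def max_curvature(self) -> float:
        """Upper bound on |∇²U| used by the dt stability precondition."""
        _, amps, widths = self._well_arrays()
        return float(np.max(amps / widths**2) + self.confine_k)

    def barrier_between(self, i: int, j: int, n_scan: int = 2001) -> float:
        """Barrier height (energy units) along the straight line joining
        well centers i and j: max U on the segment minus min U."""
        a = np.asarray(self.wells[i][0], dtype=float)
        b = np.asarray(self.wells[j][0], dtype=float)
        pts = a[None, :] + np.linspace(0, 1, n_scan)[:, None] * (b - a)[None, :]
        u = self.energy(pts)
        return float(np.max(u) - np.min(u))


@njit(cache=True)
def _langevin_kernel(x0, centers, amps, widths, k_conf, mobility, noise_amp,
                     dt, n_steps, stride, seed, r_max2):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_save = n_steps // stride + 1
    out = np.empty((n_save, 2))
    x = x0[0]
    y = x0[1]
    out[0, 0] = x
    out[0, 1] = y
    isave = 1
    for step in range(1, n_steps + 1):
        gx = k_conf * x
        gy = k_conf * y
        for w in range(centers.shape[0]):
            dx = x - centers[w, 0]
            dy = y - centers[w, 1]
            w2 = widths[w] * widths[w]
            e = amps[w] * np.exp(-(dx * dx + dy * dy) / (2.0 * w2))
            gx += e * dx / w2
            gy += e * dy / w2
        x += -mobility * gx * dt + noise_amp * np.random.normal()
        y += -mobility * gy * dt + noise_amp * np.random.normal()
        if x * x + y * y > r_max2:
            return out[:isave], step
        if step % stride == 0:
            out[isave, 0] = x
            out[isave, 1] = y
            isave += 1
    return out[:isave], 0


def gen_langevin_traj(
    pot: PotentialSpec,
    dt: float,
    n_steps: int,
    seed: int = 0,
    x0=(0.0, 0.0),
    stride: int = 1,
) -> FeatureTraj:
    """Euler–Maruyama integration of overdamped Langevin dynamics.

    x ← x − (D/k_BT)·∇U·dt + √(2·D·dt)·η with standard-normal η.
    Precondition: dt·|∇²U|·D/k_BT < 0.1 at the stiffest well, else the
    discrete update is rejected as unstable.  A trajectory leaving the
    confining region (where the harmonic term alone exceeds ~50 k_BT)
    raises :class:`UnstableIntegrationError`.  ``stride`` saves every
    k-th frame; the returned ``dt`` is the saved-frame interval.
    """
    if n_steps < 1 or stride < 1:
        raise ValueError("n_steps and stride must be >= 1")
    stability = dt * pot.max_curvature() * pot.diffusion / pot.kbt
    if stability >= 0.1:
        raise ValueError(
            f"dt too large: dt*|grad2 U|*D/kBT = {stability:.3g} >= 0.1"
        )
    centers, amps, widths = pot._well_arrays()
    if pot.confine_k > 0:
        r_max2 = 100.0 * pot.kbt / pot.confine_k
    else:
        r_max2 = (np.max(np.abs(centers)) + 20.0 * np.max(widths)) ** 2
    xy, escaped_at = _langevin_kernel(
        np.asarray(x0, dtype=float),
        centers,
        amps,
        widths,
        float(pot.confine_k),
        float(pot.diffusion / pot.kbt),
        float(np.sqrt(2.0 * pot.diffusion * dt)),
        float(dt),
        int(n_steps),
        int(stride),
        int(seed),
        float(r_max2),
    )
    if escaped_at:
        raise UnstableIntegrationError(
            f"trajectory escaped the confining region at step {escaped_at}; "
            "decrease dt or strengthen confinement"
        )
    return FeatureTraj(xy, dt * stride)


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def default_rugged_potential() -> PotentialSpec:
    """Versioned rugged-surface fixture: two deep wells (E, B) plus two
    shallow intermediate traps off the direct path."""
    import yaml

    text = resources.files("confex.data").joinpath("rugged_potential.yaml").read_text()
    cfg = yaml.safe_load(text)
    return PotentialSpec(
        wells=[((w["center"][0], w["center"][1]), w["depth"], w["width"]) for w in cfg["wells"]],
        confine_k=cfg["confine_k"],
        kbt=cfg["kbt"],
        diffusion=cfg["diffusion"],
        version=cfg["version"],
    )


def double_well_potential(depth: float = 5.0, width: float = 0.35,
                          separation: float = 2.0, confine_k: float = 1.0,
                          kbt: float = 1.0, diffusion: float = 1.0) -> PotentialSpec:
    """Symmetric double well along x with a constructed, known barrier."""
    h = separation / 2.0
    return PotentialSpec(
        wells=[((-h, 0.0), depth, width), ((h, 0.0), depth, width)],
        confine_k=confine_k,
        kbt=kbt,
        diffusion=diffusion,
    )


#: 19-state fixture topology: a metastable chain 0..18 with state 0 the
#: minor E well, states 15-18 the major B block, shallow intermediate
#: traps in between and cross edges providing alternative pathways.
_CHAIN_BARRIERS = [7.5, 6.8, 7.2, 6.5, 7.0, 6.7, 7.3, 6.6, 7.1,
                   6.9, 7.4, 6.5, 7.0, 6.8, 7.2, 6.6, 6.9, 6.7]
_EXTRA_EDGES = [(2, 7, 7.6), (4, 9, 7.3), (6, 11, 7.5),
                (8, 13, 7.2), (10, 15, 7.4), (12, 17, 7.7)]
_STATE_ENERGIES = [3.0,
                   4.6, 4.9, 4.4, 5.1, 4.7, 5.3, 4.5, 5.0, 4.8,
                   5.2, 4.6, 5.4, 4.9, 5.1,
                   0.5, 0.2, 0.0, 0.4]


def default_19state_generator(
    slowest_relaxation: float = 3e-6,
    dt: float = 7.5e-9,
) -> GeneratorMatrixSpec:
    """19-state generator with an exactly known slowest relaxation time.

    Rates follow detailed balance on an energy landscape (units of k_BT):
    k_ij = exp(−(B_ij − E_i)) for each edge with barrier energy B_ij,
    then the whole rate matrix is rescaled so the slowest relaxation
    time equals ``slowest_relaxation`` (seconds) exactly.  State 0 is
    the minor E state; states 15-18 form the major B block.
    """
    n = 19
    e = np.asarray(_STATE_ENERGIES, dtype=float)
    k = np.zeros((n, n))
    edges = [(i, i + 1, _CHAIN_BARRIERS[i]) for i in range(n - 1)] + _EXTRA_EDGES
    for i, j, barrier in edges:
        k[i, j] += np.exp(-(barrier - e[i]))
        k[j, i] += np.exp(-(barrier - e[j]))
    np.fill_diagonal(k, 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    lam = np.sort(np.real(np.linalg.eigvals(k)))[::-1]
    current = -1.0 / lam[1]  # slowest relaxation of the unscaled generator
    k *= current / slowest_relaxation
    return GeneratorMatrixSpec(n_states=n, dt=dt, rate_matrix=k)
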