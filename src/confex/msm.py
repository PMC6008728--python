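"""Markov state models from discrete-state or continuous-feature trajectories.

The pipeline mirrors standard MSM practice: frames are clustered into
microstates, transition counts at a lag time τ give a row-stochastic
transition matrix T(τ), its spectrum yields implied timescales
t_i = −τ/ln λ_i, slow eigenvectors drive micro→macro lumping, and the
stationary distribution reweights raw histograms into free-energy
surfaces.  Populations propagate as P(nτ) = P(0)·T(τ)^n.

Reversible estimation symmetrizes the count matrix, (C+Cᵀ)/2, before
row normalization; this closed form guarantees detailed balance and a
real spectrum and is adequate for well-sampled data (maximum-likelihood
detailed-balance iteration is a possible extension, not implemented).
States outside the largest strongly connected component are trimmed
before estimation and reported on the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "StateTraj",
    "FeatureTraj",
    "TransitionModel",
    "Lumping",
    "assign_microstates",
    "kabsch_rmsd",
    "count_matrix",
    "transition_matrix",
    "implied_timescales",
    "propagate",
    "lump_macrostates",
    "ck_test",
    "two_state_reduction",
    "free_energy_surface",
    "FreeEnergySurface",
    "TwoStateReduction",
]


@dataclass
class StateTraj:
    """Ordered integer microstate ids sampled every ``dt`` time units."""

    states: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if self.states.ndim != 1 or len(self.states) == 0:
            raise ValueError("states must be a non-empty 1-D sequence")
        if not np.issubdtype(self.states.dtype, np.integer):
            if np.any(self.states != np.round(self.states)):
                raise ValueError("states must be integers")
            self.states = self.states.astype(np.int64)
        if np.any(self.states < 0):
            raise ValueError("state ids must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class FeatureTraj:
    """Continuous feature vectors (frames × dims) sampled every ``dt``."""

    x: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class TransitionModel:
    """Transition matrix estimate at one lag time with its spectrum."""

    lag_time: float
    count_mat: np.ndarray
    transition_mat: np.ndarray
    stationary: np.ndarray
    eigenvalues: np.ndarray
    right_eigenvectors: np.ndarray
    left_eigenvectors: np.ndarray
    active_states: np.ndarray
    trimmed_states: np.ndarray
    reversible: bool

    def __post_init__(self) -> None:
        t = self.transition_mat
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.allclose(self.stationary @ t, self.stationary, atol=1e-10):
            raise ValueError("stationary vector must satisfy pi T = pi")

    @property
    def n_states(self) -> int:
        return self.transition_mat.shape[0]

    @property
    def timescales(self) -> np.ndarray:
        """Implied timescales t_i = −τ/ln λ_i for i ≥ 2 (t_1 is infinite).

        Complex or non-positive eigenvalues yield NaN entries."""
        lam = self.eigenvalues[1:]
        out = np.full(len(lam), np.nan)
        real = np.abs(np.imag(lam)) < 1e-12
        ok = real & (np.real(lam) > 0) & (np.real(lam) < 1 - 1e-12)
        out[ok] = -self.lag_time / np.log(np.real(lam[ok]))
        out[real & (np.real(lam) >= 1 - 1e-12)] = np.inf
        return out


@dataclass
class Lumping:
    """Surjective microstate→macrostate assignment with macro weights."""

    assignments: np.ndarray
    n_macro: int
    macro_weights: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=int)
        if set(np.unique(self.assignments)) != set(range(self.n_macro)):
            raise ValueError("every macrostate must receive at least one microstate")
        if abs(float(np.sum(self.macro_weights)) - 1.0) > 1e-9:
            raise ValueError("macro weights must sum to 1")

    def macro_sets(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignments == m) for m in range(self.n_macro)]


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def assign_microstates(features, n_micro: int, seed: int = 0):
    """K-means microstate assignment of one or several feature trajectories.

    Returns (list of StateTraj, cluster centers); initialization is fixed
    by ``seed`` so repeated calls give identical centers.
    """
    from sklearn.cluster import KMeans

    trajs = [features] if isinstance(features, FeatureTraj) else list(features)
    stacked = np.vstack([t.x for t in trajs])
    if n_micro > len(stacked):
        raise ValueError("n_micro cannot exceed the total number of frames")
    km = KMeans(n_clusters=n_micro, random_state=seed, n_init=10)
    labels = km.fit_predict(stacked)
    out = []
    offset = 0
    for t in trajs:
        out.append(StateTraj(labels[offset : offset + len(t)], t.dt))
        offset += len(t)
    if isinstance(features, FeatureTraj):
        return out[0], km.cluster_centers_
    return out, km.cluster_centers_


def kabsch_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD between two coordinate sets after optimal superposition.

    Both sets are centred, the optimal proper rotation is obtained from
    the SVD of the covariance matrix (reflections excluded by flipping
    the sign of the smallest singular vector when det < 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("coordinate sets must have identical shapes")
    if x.ndim != 2 or x.shape[0] < 3:
        raise ValueError("need at least three points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(len(s))
    flip[-1] = d
    rot = (u * flip) @ vt
    diff = xc @ rot - yc
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def count_matrix(trajs, lag_steps: int, mode: str = "sliding", n_states: int | None = None):
    """Transition count matrix C[i, j] = #{t : x_t = i, x_{t+lag} = j}.

    Sliding mode counts every start frame; strided mode advances by the
    lag, giving statistically independent counts.  Trajectories are
    never concatenated across boundaries.
    """
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    trajs = [trajs] if isinstance(trajs, StateTraj) else list(trajs)
    if n_states is None:
        n_states = int(max(t.states.max() for t in trajs)) + 1
    c = np.zeros((n_states, n_states), dtype=np.int64)
    any_pairs = False
    for t in trajs:
        s = t.states
        if len(s) <= lag_steps:
            continue
        any_pairs = True
        step = lag_steps if mode == "strided" else 1
        i = s[:-lag_steps:step]
        j = s[lag_steps::step]
        np.add.at(c, (i, j), 1)
    if not any_pairs:
        raise ValueError("lag exceeds the length of every trajectory: no counts")
    return c


def _largest_scc(c: np.ndarray):
    adj = (c > 0).astype(np.int8)
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    sizes = [
        (int(c[np.ix_(np.flatnonzero(labels == k), np.flatnonzero(labels == k))].sum()), k)
        for k in range(n_comp)
    ]
    sizes.sort(reverse=True)
    if len(sizes) > 1 and sizes[0][0] == sizes[1][0] and sizes[0][0] > 0:
        comps = [np.flatnonzero(labels == k).tolist() for _, k in sizes[:2]]
        raise ValueError(f"ambiguous largest connected component: {comps}")
    keep = np.flatnonzero(labels == sizes[0][1])
    if c[np.ix_(keep, keep)].sum() == 0:
        raise ValueError("no intra-component transitions after trimming")
    return keep


def _sorted_spectrum(t_mat: np.ndarray, pi: np.ndarray | None, reversible: bool):
    if reversible and pi is not None:
        d_half = np.sqrt(pi)
        sym = (t_mat * d_half[:, None]) / d_half[None, :]
        sym = 0.5 * (sym + sym.T)
        lam, v = np.linalg.eigh(sym)
        order = np.argsort(-lam, kind="stable")
        lam = lam[order].astype(complex)
        v = v[:, order]
        right = v / d_half[:, None]
        left = v * d_half[:, None]
    else:
        lam, right = np.linalg.eig(t_mat)
        order = np.argsort(-lam.real, kind="stable")
        lam = lam[order]
        right = right[:, order]
        left = np.linalg.inv(right).conj().T
    # deterministic sign: largest-magnitude entry of each right eigenvector positive
    for k in range(right.shape[1]):
        idx = int(np.argmax(np.abs(right[:, k])))
        ref = right[idx, k]
        if ref.real < 0 or (ref.real == 0 and ref.imag < 0):
            right[:, k] = -right[:, k]
            left[:, k] = -left[:, k]
    return lam, right, left


def transition_matrix(
    c: np.ndarray,
    reversible: bool = True,
    lag_time: float = 1.0,
) -> TransitionModel:
    """Row-stochastic transition matrix from a count matrix.

    The reversible estimator row-normalizes (C+Cᵀ)/2 and has stationary
    distribution proportional to the symmetrized row sums, satisfying
    detailed balance by construction.  The non-reversible estimator
    row-normalizes C and takes π from the leading left eigenvector.
    """
    c = np.asarray(c)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("count matrix must be square")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    keep = _largest_scc(c)
    trimmed = np.setdiff1d(np.arange(c.shape[0]), keep)
    c_act = c[np.ix_(keep, keep)].astype(float)

    if reversible:
        c_sym = 0.5 * (c_act + c_act.T)
        rows = c_sym.sum(axis=1)
        t_mat = c_sym / rows[:, None]
        pi = rows / rows.sum()
        lam, right, left = _sorted_spectrum(t_mat, pi, True)
    else:
        rows = c_act.sum(axis=1)
        t_mat = c_act / rows[:, None]
        lam, right, left = _sorted_spectrum(t_mat, None, False)
        pi = np.real(left[:, 0])
        pi = pi / pi.sum()
        if np.any(pi < -1e-12):
            raise ValueError("stationary distribution has negative entries")
        pi = np.maximum(pi, 0.0)
        pi = pi / pi.sum()

    return TransitionModel(
        lag_time=float(lag_time),
        count_mat=c,
        transition_mat=t_mat,
        stationary=pi,
        eigenvalues=lam,
        right_eigenvectors=right,
        left_eigenvectors=left,
        active_states=keep,
        trimmed_states=trimmed,
        reversible=reversible,
    )


def implied_timescales(trajs, lag_steps_list, reversible: bool = True, n_timescales: int = 5):
    """Implied-timescale table t_i(τ) over a list of lag times (in steps).

    Returns a pandas DataFrame with one row per lag; complex or
    non-positive eigenvalues appear as NaN.  A flat t_2(τ) profile
    indicates Markovian behavior at those lags.
    """
    import pandas as pd

    trajs = [trajs] if isinstance(trajs, StateTraj) else list(trajs)
    dt = trajs[0].dt
    rows = []
    for lag in lag_steps_list:
        c = count_matrix(trajs, int(lag))
        model = transition_matrix(c, reversible=reversible, lag_time=lag * dt)
        ts = model.timescales[: n_timescales - 1]
        row = {"lag_time": lag * dt, "lag_steps": int(lag)}
        for i, t_i in enumerate(ts, start=2):
            row[f"t{i}"] = t_i
        rows.append(row)
    return pd.DataFrame(rows)


def propagate(model: TransitionModel, p0, n: int):
    """P(nτ) = P(0)·T(τ)^n; probability mass is conserved."""
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 < 0) or abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("P0 must be a probability vector")
    if n < 0:
        raise ValueError("n must be >= 0")
    return p0 @ np.linalg.matrix_power(model.transition_mat, int(n))


# ---------------------------------------------------------------------------
# coarse graining
# ---------------------------------------------------------------------------

def lump_macrostates(model: TransitionModel, n_macro: int) -> Lumping:
    """Spectral (PCCA+-style) crisp lumping into ``n_macro`` macrostates.

    The top ``n_macro`` right eigenvectors span a simplex whose vertices
    correspond to maximally metastable states; vertices are located by
    the standard inner-simplex index search and each microstate is
    assigned to the vertex with the largest membership.  Deterministic
    given the model.
    """
    n = model.n_states
    if not 2 <= n_macro <= n:
        raise ValueError("n_macro must lie in [2, n_states]")
    warns: list[str] = []
    lam = model.eigenvalues
    if n_macro < n and abs(np.imag(lam[n_macro - 1])) > 1e-12:
        warns.append(f"eigenvalue {n_macro} is complex; spectral gap ill-defined")
        warnings.warn(warns[-1])
    if n_macro < n and abs(lam[n_macro - 1] - lam[n_macro]) < 1e-12:
        warns.append(f"no spectral gap between eigenvalues {n_macro} and {n_macro + 1}")
        warnings.warn(warns[-1])
    psi = np.real(model.right_eigenvectors[:, :n_macro]).copy()
    psi[:, 0] = 1.0  # constant mode

    # inner-simplex vertex search
    vertices = [int(np.argmax(np.linalg.norm(psi, axis=1)))]
    basis = psi - psi[vertices[0]]
    for _ in range(1, n_macro):
        norms = np.linalg.norm(basis, axis=1)
        v = int(np.argmax(norms))
        vertices.append(v)
        direction = basis[v] / norms[v]
        basis = basis - np.outer(basis @ direction, direction)
    chi = psi @ np.linalg.inv(psi[vertices])  # barycentric memberships
    assignments = np.argmax(chi, axis=1)
    # canonical macro labels: order by first microstate occurrence
    remap = {old: new for new, old in enumerate(dict.fromkeys(assignments.tolist()))}
    assignments = np.array([remap[s] for s in assignments])
    n_found = len(remap)
    if n_found < n_macro:
        raise ValueError("degenerate lumping: fewer macrostates than requested")
    weights = np.array(
        [model.stationary[assignments == m].sum() for m in range(n_macro)]
    )
    return Lumping(assignments=assignments, n_macro=n_macro, macro_weights=weights, warnings=warns)


def ck_test(trajs, model: TransitionModel, n_list, sets=None):
    """Chapman–Kolmogorov validation of a model against direct estimates.

    For each state set S, compares the model prediction of the
    probability to remain in S after n·τ (via P(nτ) = P(0)Tⁿ) against
    the same quantity estimated directly from the trajectories at lag
    n·τ.  P(0) weights the states of S by their empirical start counts
    at that lag, so for the non-reversible estimator the n=1 entry is
    exactly self-consistent.  Entries with no transition pairs at n·τ
    are marked unavailable.
    """
    import pandas as pd

    trajs = [trajs] if isinstance(trajs, StateTraj) else list(trajs)
    dt = trajs[0].dt
    lag_steps = int(round(model.lag_time / dt))
    if lag_steps < 1 or abs(lag_steps * dt - model.lag_time) > 1e-9 * model.lag_time:
        raise ValueError("model lag time is not a multiple of the trajectory dt")
    if sets is None:
        sets = [np.array([i]) for i in range(model.n_states)]
    sets = [np.asarray(s, dtype=int) for s in sets]

    rows = []
    for n in n_list:
        n = int(n)
        try:
            c_n = count_matrix(trajs, lag_steps * n, n_states=model.count_mat.shape[0])
        except ValueError:
            c_n = None
        t_model_n = np.linalg.matrix_power(model.transition_mat, n)
        for s_idx, s in enumerate(sets):
            # map global state ids onto the model's active set
            pos = np.searchsorted(model.active_states, s)
            valid = (pos < len(model.active_states)) & (
                model.active_states[np.minimum(pos, len(model.active_states) - 1)] == s
            )
            pos = pos[valid]
            if len(pos) == 0:
                continue
            if c_n is None:
                w = model.stationary[pos] / model.stationary[pos].sum()
                p_model = float(w @ t_model_n[np.ix_(pos, pos)].sum(axis=1))
                rows.append(
                    dict(set=s_idx, n=n, p_model=p_model, p_direct=np.nan,
                         deviation=np.nan, available=False)
                )
                continue
            c_sub = c_n[np.ix_(model.active_states[pos], model.active_states)]
            starts = c_sub.sum(axis=1).astype(float)
            if starts.sum() == 0:
                w = model.stationary[pos] / model.stationary[pos].sum()
                p_model = float(w @ t_model_n[np.ix_(pos, pos)].sum(axis=1))
                rows.append(
                    dict(set=s_idx, n=n, p_model=p_model, p_direct=np.nan,
                         deviation=np.nan, available=False)
                )
                continue
            w = starts / starts.sum()
            p_model = float(w @ t_model_n[np.ix_(pos, pos)].sum(axis=1))
            stay = c_n[np.ix_(model.active_states[pos], model.active_states[pos])].sum()
            p_direct = float(stay / starts.sum())
            rows.append(
                dict(set=s_idx, n=n, p_model=p_model, p_direct=p_direct,
                     deviation=abs(p_model - p_direct), available=True)
            )
    return pd.DataFrame(rows)


@dataclass
class TwoStateReduction:
    kex: float
    p_e: float
    kex_sigma: float | None = None
    pe_sigma: float | None = None
    t2: float | None = None


def two_state_reduction(
    model: TransitionModel,
    lumping: Lumping | None,
    e_set,
    b_set,
    trajs=None,
    n_boot: int = 0,
    seed: int = 0,
    reversible: bool = True,
) -> TwoStateReduction:
    """Reduce a many-state model to effective two-state (kex, pE).

    1/kex is the slowest implied timescale t_2 and
    pE = π(E)/(π(E)+π(B)); E and B are macrostate sets when a lumping is
    given, else microstate sets (indices into the active set).  With
    trajectories supplied, bootstrap resampling over whole trajectories
    provides σ estimates.
    """
    e_set = np.asarray(e_set, dtype=int)
    b_set = np.asarray(b_set, dtype=int)
    if len(e_set) == 0 or len(b_set) == 0 or np.intersect1d(e_set, b_set).size:
        raise ValueError("E and B sets must be disjoint and non-empty")

    def reduce_one(m: TransitionModel) -> tuple[float, float]:
        t2 = m.timescales[0]
        if not np.isfinite(t2) or t2 <= 0:
            raise ValueError("slowest implied timescale is not real/positive")
        if lumping is not None:
            micro_e = np.concatenate([np.flatnonzero(lumping.assignments == m_i) for m_i in e_set])
            micro_b = np.concatenate([np.flatnonzero(lumping.assignments == m_i) for m_i in b_set])
        else:
            micro_e, micro_b = e_set, b_set
        # original ids -> positions in the (possibly trimmed) active set
        pos_e = np.searchsorted(m.active_states, np.intersect1d(micro_e, m.active_states))
        pos_b = np.searchsorted(m.active_states, np.intersect1d(micro_b, m.active_states))
        if len(pos_e) == 0 or len(pos_b) == 0:
            raise ValueError("E or B set entirely trimmed from the active set")
        pi_e = m.stationary[pos_e].sum()
        pi_b = m.stationary[pos_b].sum()
        return 1.0 / t2, pi_e / (pi_e + pi_b)

    kex, p_e = reduce_one(model)
    kex_sigma = pe_sigma = None
    if n_boot and trajs is not None:
        rng = np.random.default_rng(seed)
        trajs = list(trajs)
        dt = trajs[0].dt
        lag_steps = int(round(model.lag_time / dt))
        kex_s, pe_s = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, len(trajs), size=len(trajs))
            try:
                c = count_matrix([trajs[i] for i in pick], lag_steps,
                                 n_states=model.count_mat.shape[0])
                m_b = transition_matrix(c, reversible=reversible, lag_time=model.lag_time)
                if m_b.n_states != model.n_states:
                    continue
                k_b, p_b = reduce_one(m_b)
            except ValueError:
                continue
            kex_s.append(k_b)
            pe_s.append(p_b)
        if len(kex_s) >= 2:
            kex_sigma = float(np.std(kex_s, ddof=1))
            pe_sigma = float(np.std(pe_s, ddof=1))
    return TwoStateReduction(kex=float(kex), p_e=float(p_e),
                             kex_sigma=kex_sigma, pe_sigma=pe_sigma,
                             t2=float(1.0 / kex))


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    f_grid: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    pmf_x: np.ndarray
    pmf_y: np.ndarray
    degenerate: bool = False


def free_energy_surface(
    features,
    assignments,
    stationary,
    bins=50,
    kbt: float = 1.0,
) -> FreeEnergySurface:
    """π-reweighted 2-D free-energy surface with 1-D PMF projections.

    Each frame gets weight π(its microstate)/(frames in that microstate),
    so the surface reflects the MSM stationary distribution rather than
    raw sampling.  F = −k_BT·ln(weighted histogram) shifted so the
    minimum is zero; empty bins are +inf.  1-D projections sum
    probability (not F) over the other axis before taking the log.
    """
    trajs = [features] if isinstance(features, FeatureTraj) else list(features)
    xy = np.vstack([t.x for t in trajs])
    if xy.shape[1] != 2:
        raise ValueError("free-energy surface requires 2-D features")
    assign = np.concatenate(
        [np.asarray(a) for a in ([assignments] if np.ndim(assignments[0]) == 0 else assignments)]
    )
    if len(assign) != len(xy):
        raise ValueError("assignments must label every frame")
    if np.ndim(bins) == 0 and bins < 2:
        raise ValueError("need at least 2 bins per axis")

    stationary = np.asarray(stationary, dtype=float)
    counts = np.bincount(assign, minlength=len(stationary)).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_frame = np.where(counts[assign] > 0, stationary[assign] / counts[assign], 0.0)

    hist, x_edges, y_edges = np.histogram2d(xy[:, 0], xy[:, 1], bins=bins, weights=per_frame)
    total = hist.sum()
    if total <= 0:
        raise ValueError("all frame weights are zero")
    prob = hist / total
    degenerate = np.count_nonzero(prob) <= 1
    if degenerate:
        warnings.warn("all frames fall in a single bin: degenerate surface")
    with np.errstate(divide="ignore"):
        f = -kbt * np.log(prob)
    f -= np.min(f)

    def project(axis):
        p = prob.sum(axis=axis)
        with np.errstate(divide="ignore"):
            pmf = -kbt * np.log(p)
        return pmf - np.min(pmf)

    return FreeEnergySurface(
        f_grid=f,
        x_edges=x_edges,
        y_edges=y_edges,
        pmf_x=project(1),
        pmf_y=project(0),
        degenerate=bool(degenerate),
    )
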