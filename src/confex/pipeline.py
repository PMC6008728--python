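"""Config-driven pipeline tying the analysis stages together.

Two natural chains exist: dispersion data → global two-state fit →
Arrhenius thermokinetics, and trajectories → MSM → TPT → barrier.
``run_pipeline`` executes any requested subset in dependency order,
seeds every stochastic stage from the config, and records a run report
whose numeric results all trace to stage output files.  A failed stage
marks its downstream stages skipped and the run as failed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, cpmg, io, msm, synthetic, thermokinetics as tk, tpt as tptmod
from .constants import KELVIN_OFFSET, R_GAS

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "parse_temperature"]

STAGE_ORDER = [
    "simulate_cpmg", "fit_cpmg", "arrhenius",
    "gen_traj", "build_msm", "tpt", "barrier",
]
_DEPENDENCIES = {
    "fit_cpmg": ["simulate_cpmg"],
    "arrhenius": ["fit_cpmg"],
    "build_msm": ["gen_traj"],
    "tpt": ["build_msm"],
    "barrier": ["tpt"],
}


def parse_temperature(text) -> float:
    """Parse a temperature with explicit unit suffix ('37C' or '310.15K')."""
    if isinstance(text, (int, float)):
        raise ValueError("temperature needs an explicit unit suffix, e.g. '37C' or '310.15K'")
    text = text.strip()
    if text.endswith("C"):
        return float(text[:-1]) + KELVIN_OFFSET
    if text.endswith("K"):
        return float(text[:-1])
    raise ValueError(f"temperature {text!r} needs a unit suffix 'C' or 'K'")


@dataclass
class PipelineConfig:
    stages: list[str]
    outdir: Path
    seed: int = 0
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        return cls(
            stages=list(cfg["stages"]),
            outdir=cfg.get("outdir", "."),
            seed=int(cfg.get("seed", 0)),
            options={k: v for k, v in cfg.items() if k not in ("stages", "outdir", "seed")},
        )

    def config_hash(self) -> str:
        canon = repr(
            (sorted(self.stages), str(self.outdir), self.seed,
             sorted((k, repr(v)) for k, v in self.options.items()))
        )
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    version: str
    config_hash: str
    seed: int
    stages: dict
    ok: bool

    def to_dict(self) -> dict:
        return dict(version=self.version, config_hash=self.config_hash,
                    seed=self.seed, stages=self.stages, ok=self.ok)


def _validate_inputs(config: PipelineConfig) -> None:
    for stage in config.stages:
        opts = config.options.get(stage, {})
        for key in ("data", "rates", "msm", "trajs", "config"):
            if key in opts and str(opts[key]) != "experimental":
                p = Path(opts[key])
                produced = any(
                    dep in config.stages for dep in _DEPENDENCIES.get(stage, [])
                )
                if not p.exists() and not produced:
                    raise FileNotFoundError(f"stage {stage}: input path {p} does not exist")


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate_cpmg(opts: dict, outdir: Path, seed: int) -> dict:
    truth = synthetic.ExchangeTruth(
        kex=float(opts.get("kex", 2000.0)),
        p_e=float(opts.get("p_e", 0.03)),
        dw_ppm={str(k): float(v) for k, v in opts.get("dw_ppm", {"R1": 2.0}).items()},
        r2_0=float(opts.get("r2_0", 10.0)),
        nucleus=opts.get("nucleus", "15N"),
        fields=tuple(opts.get("fields", [11.7])),
        temperature_k=parse_temperature(opts.get("temperature", "25C")),
    )
    t_cpmg = float(opts.get("t_cpmg", 0.02))
    n_points = int(opts.get("n_points", 15))
    nu = np.rint(np.linspace(1, n_points, n_points)) / t_cpmg
    ds = synthetic.gen_cpmg_dataset(
        truth, nu, t_cpmg,
        noise_sd=float(opts.get("noise_sd", synthetic.DEFAULT_R2EFF_NOISE_SD)),
        seed=seed,
    )
    out_csv = outdir / opts.get("out", "dispersion.csv")
    io.write_dispersion_csv(out_csv, ds)
    io.write_json(out_csv.with_suffix(".truth.json"), ds.truth)
    return {"dispersion_csv": str(out_csv)}


def _stage_fit_cpmg(opts: dict, outdir: Path, seed: int) -> dict:
    data = Path(opts.get("data", outdir / "dispersion.csv"))
    ds = io.read_dispersion_csv(data)
    fit = cpmg.fit_two_state_global(ds)
    payload = {
        "kex_s1": fit.kex,
        "p_minor": fit.p_minor,
        "dw_ppm": fit.dw_ppm,
        "r2_0": {"|".join(map(str, k)): v for k, v in fit.r2_0.items()},
        "chi2": fit.chi2,
        "redchi": fit.redchi,
        "success": fit.success,
        "unidentifiable": fit.unidentifiable,
    }
    n_boot = int(opts.get("boot", 0))
    if n_boot:
        payload["bootstrap"] = cpmg.bootstrap_errors(ds, fit, n_boot=n_boot, seed=seed)
    out = outdir / opts.get("out", "fit.json")
    io.write_json(out, payload)
    return {"fit_json": str(out)}


def _stage_arrhenius(opts: dict, outdir: Path, seed: int) -> dict:
    rates = opts.get("rates", "experimental")
    series = io.experimental_rates() if str(rates) == "experimental" else io.read_rate_series(rates)
    fit_be = tk.fit_arrhenius(series.temperature_k, series.k_be, series.kbe_sigma)
    fit_eb = tk.fit_arrhenius(series.temperature_k, series.k_eb, series.keb_sigma)
    temps = [parse_temperature(t) for t in opts.get("extrapolate", ["37C", "50C"])]
    thermo = tk.equilibrium_thermo(fit_be, fit_eb, temps)
    payload = {
        "arrhenius": {
            "be": {"ea_j_mol": fit_be.ea, "ln_a": fit_be.ln_a},
            "eb": {"ea_j_mol": fit_eb.ea, "ln_a": fit_eb.ln_a},
        },
        "dh_kj_mol": thermo.dh / 1000.0,
        "dh_act_kj_mol": fit_be.ea / 1000.0,
        "extrapolations": {},
        "seed": seed,
    }
    for t_k in temps:
        k_be, s_be = tk.extrapolate_rate(fit_be, t_k)
        k_eb, s_eb = tk.extrapolate_rate(fit_eb, t_k)
        kbt_kj = R_GAS * t_k / 1000.0
        payload["extrapolations"][f"{t_k:.2f}K"] = {
            "k_be_s1": k_be, "k_be_sigma_s1": s_be,
            "k_eb_s1": k_eb, "k_eb_sigma_s1": s_eb,
            "kex_s1": k_be + k_eb,
            "p_e_percent": 100.0 * k_be / (k_be + k_eb),
            "lifetime_e_us": 1e6 * tk.lifetime(k_eb),
            "dg_kj_mol": thermo.dg[t_k] / 1000.0,
            "dg_kbt": thermo.dg[t_k] / 1000.0 / kbt_kj,
            "ds_j_mol_k": thermo.ds[t_k],
        }
    out = outdir / opts.get("out", "thermo.json")
    io.write_json(out, payload)
    return {"thermo_json": str(out)}


def _stage_gen_traj(opts: dict, outdir: Path, seed: int) -> dict:
    kind = opts.get("kind", "markov")
    traj_dir = outdir / opts.get("out", "trajs")
    traj_dir.mkdir(parents=True, exist_ok=True)
    n_traj = int(opts.get("n_traj", 10))
    n_steps = int(opts.get("n_steps", 10_000))
    paths = []
    if kind == "markov":
        spec = synthetic.default_19state_generator()
        for i in range(n_traj):
            traj = synthetic.gen_markov_traj(spec, n_steps, seed=seed + i, start="stationary")
            p = traj_dir / f"traj_{i:03d}.csv"
            io.write_state_traj(p, traj)
            paths.append(str(p))
    elif kind == "langevin":
        pot = synthetic.default_rugged_potential()
        dt = float(opts.get("dt", 1e-3))
        for i in range(n_traj):
            traj = synthetic.gen_langevin_traj(
                pot, dt, n_steps, seed=seed + i, x0=(-1.2, 0.0),
                stride=int(opts.get("stride", 1)),
            )
            p = traj_dir / f"traj_{i:03d}.csv"
            io.write_feature_traj(p, traj)
            paths.append(str(p))
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    return {"traj_dir": str(traj_dir), "n_traj": n_traj}


def _stage_build_msm(opts: dict, outdir: Path, seed: int) -> dict:
    traj_dir = Path(opts.get("trajs", outdir / "trajs"))
    paths = sorted(traj_dir.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no trajectory CSVs in {traj_dir}")
    first = paths[0].read_text().splitlines()
    is_feature = any("," in ln for ln in first if not ln.startswith("#"))
    if is_feature:
        feats = [io.read_feature_traj(p) for p in paths]
        n_micro = int(opts.get("n_micro", 200))
        strajs, centers = msm.assign_microstates(feats, n_micro, seed=seed)
    else:
        strajs = [io.read_state_traj(p) for p in paths]
        centers = None
    dt = strajs[0].dt
    lag_time = float(opts.get("lag", 3 * dt))
    lag_steps = max(1, int(round(lag_time / dt)))
    c = msm.count_matrix(strajs, lag_steps)
    model = msm.transition_matrix(c, reversible=bool(opts.get("reversible", True)),
                                  lag_time=lag_steps * dt)
    n_macro = int(opts.get("n_macro", 0))
    lumping = msm.lump_macrostates(model, n_macro) if n_macro else None
    payload = {
        "lag_time": model.lag_time,
        "transition_matrix": model.transition_mat,
        "stationary": model.stationary,
        "eigenvalues": np.real(model.eigenvalues),
        "implied_timescales": model.timescales,
        "active_states": model.active_states,
        "trimmed_states": model.trimmed_states,
        "reversible": model.reversible,
    }
    if lumping is not None:
        payload["lumping"] = lumping.assignments
        payload["macro_weights"] = lumping.macro_weights
    if centers is not None:
        payload["centers"] = centers
    out = outdir / opts.get("out", "msm.json")
    io.write_json(out, payload)
    return {"msm_json": str(out)}


def _load_model(path) -> msm.TransitionModel:
    d = io.read_json(path)
    t = np.asarray(d["transition_matrix"], dtype=float)
    t = t / t.sum(axis=1, keepdims=True)
    c = np.rint(t * 1e9).astype(np.int64)  # counts are not serialized; synthesize
    pi = np.asarray(d["stationary"], dtype=float)
    lam, right, left = msm._sorted_spectrum(t, pi if d.get("reversible", True) else None,
                                            d.get("reversible", True))
    return msm.TransitionModel(
        lag_time=float(d["lag_time"]), count_mat=c, transition_mat=t,
        stationary=pi / pi.sum(), eigenvalues=lam, right_eigenvectors=right,
        left_eigenvectors=left,
        active_states=np.asarray(d["active_states"], dtype=int),
        trimmed_states=np.asarray(d.get("trimmed_states", []), dtype=int),
        reversible=bool(d.get("reversible", True)),
    )


def _stage_tpt(opts: dict, outdir: Path, seed: int) -> dict:
    model = _load_model(Path(opts.get("msm", outdir / "msm.json")))
    source = [int(s) for s in str(opts.get("source", "0")).split(",")]
    sink = [int(s) for s in str(opts.get("sink", "")).split(",") if s != ""]
    if not sink:
        sink = [model.n_states - 1]
    comm = tptmod.committors(model, source, sink)
    flux = tptmod.reactive_flux(model, comm)
    pathways = tptmod.decompose_pathways(flux, stop_fraction=float(opts.get("stop_fraction", 0.999)))
    payload = {
        "q_plus": comm.q_plus,
        "q_minus": comm.q_minus,
        "net_flux": flux.net,
        "total_flux": flux.total,
        "pathways": [
            {"states": list(p), "flux": f, "fraction": f / flux.total}
            for p, f in pathways.paths
        ],
        "residual_fraction": pathways.residual_flux / flux.total,
    }
    out = outdir / opts.get("out", "tpt.json")
    io.write_json(out, payload)
    return {"tpt_json": str(out)}


def _stage_barrier(opts: dict, outdir: Path, seed: int) -> dict:
    t_k = parse_temperature(opts.get("temperature", "37C"))
    est = tk.barrier_from_tpt(float(opts["k"]), float(opts["tau_tpt"]), t_k)
    payload = {
        "dg_act_kj_mol": est.dg_j_mol / 1000.0,
        "dg_act_kbt": est.dg_kbt,
        "barrierless": est.barrierless,
        "temperature_K": est.temperature_k,
    }
    out = outdir / opts.get("out", "barrier.json")
    io.write_json(out, payload)
    return {"barrier_json": str(out)}


_STAGE_FUNCS = {
    "simulate_cpmg": _stage_simulate_cpmg,
    "fit_cpmg": _stage_fit_cpmg,
    "arrhenius": _stage_arrhenius,
    "gen_traj": _stage_gen_traj,
    "build_msm": _stage_build_msm,
    "tpt": _stage_tpt,
    "barrier": _stage_barrier,
}


def run_pipeline(config: PipelineConfig | dict) -> RunReport:
    """Execute the requested stages in dependency order.

    All randomness derives from ``config.seed``; running the same config
    twice produces byte-identical outputs.  A stage failure marks
    downstream stages as skipped and the report as failed.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    _validate_inputs(config)
    config.outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    failed: set[str] = set()
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        blocked = [d for d in _DEPENDENCIES.get(stage, [])
                   if d in config.stages and d in failed]
        if blocked:
            stages[stage] = {"status": "skipped", "blocked_by": blocked}
            failed.add(stage)
            continue
        try:
            outputs = _STAGE_FUNCS[stage](
                config.options.get(stage, {}), config.outdir, config.seed
            )
            stages[stage] = {"status": "ok", "outputs": outputs}
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed
            stages[stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
            failed.add(stage)
    report = RunReport(
        version=__version__,
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
        ok=not failed,
    )
    io.write_json(config.outdir / "report.json", report.to_dict())
    return report
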