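"""SC-conditioned generative models of regional activity and BOLD.

Five dynamical regimes take a structural connectome as input and emit a
functional connectivity pattern:

- ``sar``: spatial autoregressive model; FC follows in closed form from the
  covariance ``sigma^2 (I - G W)^-1 (I - G W)^-T``,
- ``rate``: linear stochastic rate model,
- ``wilson_cowan``: excitatory/inhibitory pair per region with sigmoidal
  gain,
- ``kuramoto``: phase oscillators with heterogeneous natural frequencies
  (observable sin(phase)),
- ``fitzhugh_nagumo``: fast-slow excitable pair per region (observable the
  fast variable).

In every model the connectome enters as ``G * W`` with ``W`` the
row-normalized SC and ``G`` a global coupling scalar, tuned by grid search
against a target FC.  All models but the SAR produce neuronal activity that
is passed through the Balloon-Windkessel hemodynamic model, global-signal
regressed, and correlated to give simulated FC; the SAR's FC is analytic and
skips both hemodynamics and GSR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import _integrators as _ki
from ._rng import OP_DYNAMICS, kernel_seed, substream
from .cohort import SCMatrix
from .errors import DivergenceError, StabilityError
from .fc import BOLDRun, ConnectivityVector, global_signal_regression, pearson_fc, vectorize_upper

logger = logging.getLogger(__name__)

MODEL_NAMES = ("sar", "rate", "wilson_cowan", "kuramoto", "fitzhugh_nagumo")

#: regime-specific constants (documented defaults, all overridable)
DEFAULT_PARAMS: dict[str, dict[str, float]] = {
    "sar": {"sigma": 1.0},
    "rate": {"tau": 1.0},
    # P below the oscillation threshold puts each node in a noise-driven
    # fluctuation regime, so covariance is shaped by inter-regional input
    # rather than by the local limit cycle
    "wilson_cowan": {
        "tau_e": 0.01, "tau_i": 0.01,
        "c1": 16.0, "c2": 12.0, "c3": 15.0, "c4": 3.0,
        "a_e": 1.3, "th_e": 4.0, "a_i": 2.0, "th_i": 3.7, "P": 0.8,
    },
    "kuramoto": {"f_mean": 0.05, "f_sd": 0.01},
    "fitzhugh_nagumo": {"a": 0.7, "b": 0.8, "tau_w": 12.5, "I_ext": 0.4, "speed": 1.0},
}

DEFAULT_NOISE: dict[str, float] = {
    "sar": 1.0,
    "rate": 0.1,
    "wilson_cowan": 0.03,
    "kuramoto": 0.3,
    "fitzhugh_nagumo": 0.05,
}

_MODEL_ID = {name: i for i, name in enumerate(MODEL_NAMES)}


@dataclass
class ModelConfig:
    """Integration and coupling configuration for one simulation run."""

    model_name: str
    global_coupling: float = 0.5
    noise_sd: float | None = None
    dt: float = 0.001
    duration: float = 60.0
    burn_in: float = 10.0
    dt_sample: float = 0.01
    model_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.model_name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model_name!r}; choose from {MODEL_NAMES}")
        if self.global_coupling < 0:
            raise ValueError("global_coupling must be nonnegative")
        if self.dt <= 0 or self.dt > self.dt_sample:
            raise ValueError("require 0 < dt <= dt_sample")
        if self.duration <= self.burn_in:
            raise ValueError("duration must exceed burn_in")
        if self.noise_sd is None:
            self.noise_sd = DEFAULT_NOISE[self.model_name]
        merged = dict(DEFAULT_PARAMS[self.model_name])
        merged.update(self.model_params)
        self.model_params = merged


@dataclass
class NeuralTimeSeries:
    """Regions x samples observable of a dynamics model."""

    values: np.ndarray
    dt_sample: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("neural values must be finite")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel constants (signal decay kappa, feedback gamma,
    transit time tau, stiffness alpha, resting oxygen extraction E0,
    resting venous volume V0)."""

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must be in (0, 1)")
        for name in ("kappa", "gamma", "tau", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def row_normalize(w: np.ndarray) -> np.ndarray:
    """Normalize rows to unit sum; all-zero rows stay zero."""
    w = np.asarray(w, dtype=float)
    sums = w.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, w / sums, 0.0)
    return out


def sar_fc(sc: SCMatrix, coupling: float, noise_sd: float = 1.0) -> np.ndarray:
    """Analytic FC of the spatial autoregressive model.

    Covariance ``sigma^2 (I - G W)^-1 (I - G W)^-T`` with W the
    row-normalized SC, converted to correlation.  Requires the spectral
    radius of ``G W`` to be below 1.
    """
    W = row_normalize(sc.weights)
    n = W.shape[0]
    radius = float(np.max(np.abs(np.linalg.eigvals(coupling * W))))
    if radius >= 1.0:
        raise StabilityError(
            f"SAR unstable: spectral radius of G*W is {radius:.4f} >= 1 at G={coupling}"
        )
    A = np.linalg.inv(np.eye(n) - coupling * W)
    cov = noise_sd**2 * A @ A.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def simulate_dynamics(sc: SCMatrix, config: ModelConfig) -> NeuralTimeSeries:
    """Integrate one dynamics model on an SC matrix.

    Euler-Maruyama at step ``dt``; the burn-in is discarded and the
    observable is recorded every ``dt_sample``.  Identical (seed, config)
    pairs give identical output.  The SAR model has no time-domain form
    here; request one of the four dynamical regimes.
    """
    name = config.model_name
    if name == "sar":
        raise ValueError("the SAR model is analytic; use sar_fc() or simulate_fc()")
    W = np.ascontiguousarray(row_normalize(sc.weights))
    n = W.shape[0]
    n_steps = int(round(config.duration / config.dt))
    burn_steps = int(round(config.burn_in / config.dt))
    sample_every = max(1, int(round(config.dt_sample / config.dt)))
    n_out = (n_steps - burn_steps) // sample_every
    if n_out < 1:
        raise ValueError("duration minus burn_in shorter than one sample interval")
    out = np.empty((n, n_out))
    p = config.model_params
    G = config.global_coupling
    sd = config.noise_sd
    ks = kernel_seed(config.seed, OP_DYNAMICS, _MODEL_ID[name])
    common = (sd, config.dt, n_steps, burn_steps, sample_every, ks, out)

    if name == "rate":
        code = _ki.rate_kernel(W, G, p["tau"], *common)
    elif name == "kuramoto":
        rng = substream(config.seed, OP_DYNAMICS, _MODEL_ID[name], 1)
        omega = 2 * np.pi * rng.normal(p["f_mean"], p["f_sd"], n)
        code = _ki.kuramoto_kernel(W, G, omega, *common)
    elif name == "wilson_cowan":
        code = _ki.wilson_cowan_kernel(
            W, G, p["tau_e"], p["tau_i"], p["c1"], p["c2"], p["c3"], p["c4"],
            p["a_e"], p["th_e"], p["a_i"], p["th_i"], p["P"], *common,
        )
    elif name == "fitzhugh_nagumo":
        code = _ki.fitzhugh_nagumo_kernel(
            W, G, p["a"], p["b"], p["tau_w"], p["I_ext"], p["speed"], *common
        )
    else:  # pragma: no cover - guarded in ModelConfig
        raise ValueError(f"unknown model {name!r}")
    if code >= 0:
        t_blow = code * config.dt
        raise DivergenceError(
            f"{name} integration diverged at t={t_blow:.3f} s (G={G})", time=t_blow
        )
    return NeuralTimeSeries(values=out, dt_sample=config.dt_sample)


def balloon_windkessel(
    neural: NeuralTimeSeries,
    params: HemodynamicParams | None = None,
    tr: float = 3.29,
) -> BOLDRun:
    """Map neuronal activity to BOLD via the Balloon-Windkessel system.

    The four-state hemodynamic ODE (vasodilatory signal, inflow, venous
    volume, deoxyhemoglobin) is integrated per region at the neural sampling
    step, then the percent-signal-change read-out is sampled every ``tr``
    seconds on the same grid (so doubling ``tr`` takes every other sample).
    """
    params = params or HemodynamicParams()
    if tr < neural.dt_sample:
        raise ValueError("tr must be at least the neural sampling interval")
    z = np.ascontiguousarray(neural.values)
    dense = np.empty_like(z)
    code = _ki.balloon_kernel(
        z, params.kappa, params.gamma, params.tau, params.alpha, params.E0, params.V0,
        neural.dt_sample, dense,
    )
    if code >= 0:
        T = z.shape[1]
        t_blow = (code % T) * neural.dt_sample
        raise DivergenceError(
            f"hemodynamic state diverged in region {code // T} at t={t_blow:.2f} s", time=t_blow
        )
    stride = int(round(tr / neural.dt_sample))
    sampled = dense[:, ::stride]
    if sampled.shape[1] < 2:
        raise ValueError("run too short: fewer than 2 BOLD samples at this tr")
    return BOLDRun(values=sampled, tr=tr, gsr_applied=False)


#: BOLD seconds discarded after the hemodynamic onset transient
HEMODYNAMIC_SETTLE = 20.0


def simulate_fc(
    model_name: str,
    sc: SCMatrix,
    config: ModelConfig | None = None,
    tr: float = 3.29,
    n_samples: int | None = None,
    apply_gsr: bool = True,
) -> ConnectivityVector:
    """Full simulation chain from SC to a vectorized cFC pattern.

    dynamics -> Balloon-Windkessel -> global-signal regression -> Pearson
    correlation -> upper-triangle vectorization.  The SAR model bypasses
    simulation via its analytic correlation matrix, without GSR.  The first
    ``HEMODYNAMIC_SETTLE`` seconds of BOLD are discarded; ``n_samples``
    truncates to a fixed run length.
    """
    if config is not None and config.model_name != model_name:
        config = replace(config, model_name=model_name)
    if model_name == "sar":
        cfg = config or ModelConfig(model_name="sar")
        corr = sar_fc(sc, cfg.global_coupling, cfg.model_params.get("sigma", 1.0))
        return vectorize_upper(corr, sc.atlas)
    cfg = config or ModelConfig(model_name=model_name)
    neural = simulate_dynamics(sc, cfg)
    bold = balloon_windkessel(neural, tr=tr)
    n_drop = int(np.ceil(HEMODYNAMIC_SETTLE / tr))
    vals = bold.values[:, n_drop:]
    if n_samples is not None:
        if vals.shape[1] < n_samples:
            raise ValueError(
                f"run yields {vals.shape[1]} BOLD samples after settle, need {n_samples}; "
                "increase config.duration"
            )
        vals = vals[:, :n_samples]
    run = BOLDRun(values=vals, tr=tr, gsr_applied=False)
    if apply_gsr:
        run = global_signal_regression(run)
    return vectorize_upper(pearson_fc(run), sc.atlas)


def config_for_samples(
    model_name: str,
    n_samples: int,
    tr: float = 3.29,
    seed: int = 0,
    global_coupling: float | None = None,
    **overrides,
) -> ModelConfig:
    """A ModelConfig whose duration yields ``n_samples`` BOLD samples."""
    burn_in = overrides.pop("burn_in", 10.0)
    duration = burn_in + HEMODYNAMIC_SETTLE + (n_samples + 2) * tr
    kwargs = dict(model_name=model_name, duration=duration, burn_in=burn_in, seed=seed)
    if global_coupling is not None:
        kwargs["global_coupling"] = global_coupling
    kwargs.update(overrides)
    return ModelConfig(**kwargs)


def tune_global_coupling(
    model_name: str,
    sc: SCMatrix,
    target_fc_vector: ConnectivityVector | np.ndarray,
    grid,
    config: ModelConfig | None = None,
    tr: float = 3.29,
    n_samples: int | None = None,
) -> float:
    """Grid-search the coupling maximizing correlation with a target FC.

    Every grid point is evaluated with the same seed and logged; ties are
    broken toward the smaller coupling.  SAR grid points violating the
    stability bound are skipped; if every point is unstable the stability
    error propagates.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("coupling grid is empty")
    target = np.asarray(
        target_fc_vector.values if isinstance(target_fc_vector, ConnectivityVector)
        else target_fc_vector,
        dtype=float,
    )
    best_g, best_r = None, -np.inf
    last_err: StabilityError | None = None
    for g in sorted(grid):
        try:
            cfg = replace(config, global_coupling=g, model_name=model_name) if config else None
            vec = simulate_fc(
                model_name, sc,
                cfg or ModelConfig(model_name=model_name, global_coupling=g),
                tr=tr, n_samples=n_samples,
            )
        except StabilityError as err:
            logger.info("G=%g unstable, skipped (%s)", g, err)
            last_err = err
            continue
        r = float(np.corrcoef(vec.values, target)[0, 1])
        logger.info("tune %s: G=%g -> r=%.4f", model_name, g, r)
        if r > best_r:
            best_g, best_r = g, r
    if best_g is None:
        raise last_err if last_err is not None else ValueError("no evaluable grid point")
    return float(best_g)
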