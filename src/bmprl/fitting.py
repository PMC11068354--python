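"""Maximum-likelihood fitting and BIC model comparison.

Sessions from one animal and condition are pooled: parameters are shared
across sessions while the value state resets at every session start.  The
summed negative log-likelihood is minimised with bounded L-BFGS-B from
multiple random starting points inside the parameter box.  BIC is computed
with n = total number of modelled choices.

Two-stage ketamine fitting: a converged differential-forgetting fit to the
saline sessions supplies the frozen baseline binding of a K-model; only the
K-model's deviation parameters are optimised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .rl_models import (FAMILY_FREE, BASELINE_PARAM_NAMES, ModelSpec, ParamSet,
                        SessionArrays, pack_sessions, pooled_nll)

log = logging.getLogger(__name__)

#: optimisation box per parameter; rates and mixture weights live on [0, 1],
#: outcome updates and shifts on a wide symmetric box
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha_F": (0.0, 1.0),
    "alpha_F_C": (0.0, 1.0),
    "alpha_F_UC": (0.0, 1.0),
    "alpha_L": (0.0, 1.0),
    "epsilon": (0.0, 1.0),
    "rho": (0.0, 1.0),
    "phi": (0.0, 1.0),
    "tau": (0.0, 10.0),
    "beta": (1e-3, 20.0),
    "delta_gain": (-10.0, 10.0),
    "delta_neutral": (-10.0, 10.0),
    "delta_loss": (-10.0, 10.0),
    "lambda_": (-10.0, 10.0),
    "omega1": (-10.0, 10.0),
    "omega2": (-10.0, 10.0),
    "omega3": (-10.0, 10.0),
    "k": (-10.0, 10.0),
    "k1": (-10.0, 10.0),
    "k2": (-10.0, 10.0),
}

#: random restarts are drawn inside this (tighter) box so wide-box parameters
#: start at plausible magnitudes
INIT_CLIP = (-3.0, 3.0)


@dataclass
class FitConfig:
    n_restarts: int = 20
    tolerance: float = 1e-8
    seed: int = 0
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    def bound(self, name: str) -> tuple[float, float]:
        return self.bounds.get(name, PARAM_BOUNDS[name])


@dataclass
class FitResult:
    spec: ModelSpec
    params: ParamSet
    nll: float
    n_trials: int
    n_free: int
    bic: float
    converged: bool
    restart_spread: float


def bic(nll: float, n_free: int, n_trials: int) -> float:
    """Bayesian information criterion, k*ln(n) + 2*nll (lower is better)."""
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    return n_free * np.log(n_trials) + 2.0 * nll


def _base_params(spec: ModelSpec, fixed: dict[str, float] | None) -> ParamSet:
    params = ParamSet()
    if fixed:
        params = replace(params, **fixed)
    return params


def fit_mle(sessions, spec: ModelSpec, cfg: FitConfig | None = None, *,
            fixed: dict[str, float] | None = None) -> FitResult:
    """Fit a model's free parameters to pooled sessions by maximum likelihood.

    ``fixed`` optionally pins named parameters (removing them from the free
    set); a spec whose free set is empty is evaluated, not optimised.
    """
    cfg = cfg or FitConfig()
    data = sessions if isinstance(sessions, SessionArrays) else pack_sessions(sessions)
    free = [name for name in spec.free_params if not (fixed and name in fixed)]
    base = _base_params(spec, fixed)
    if not free:
        nll = pooled_nll(data, spec, base)
        return FitResult(spec, base, nll, data.n_trials, 0,
                         bic(nll, 0, data.n_trials), True, 0.0)

    lo = np.array([cfg.bound(n)[0] for n in free])
    hi = np.array([cfg.bound(n)[1] for n in free])

    def objective(theta: np.ndarray) -> float:
        params = replace(base, **dict(zip(free, theta)))
        return pooled_nll(data, spec, params)

    rng = np.random.default_rng(cfg.seed)
    init_lo = np.maximum(lo, INIT_CLIP[0])
    init_hi = np.minimum(hi, INIT_CLIP[1])
    starts = [0.5 * (init_lo + init_hi)]
    starts += [rng.uniform(init_lo, init_hi) for _ in range(cfg.n_restarts - 1)]

    results = []
    for x0 in starts:
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                bounds=list(zip(lo, hi)),
                                options={"ftol": cfg.tolerance, "maxiter": 500})
        results.append(res)
    converged = [r for r in results if r.success]
    if not converged:
        log.warning("no restart converged for %s; returning best attempt", spec.family)
    pool = converged or results
    best = min(pool, key=lambda r: r.fun)
    spread = max(r.fun for r in pool) - min(r.fun for r in pool)
    params = replace(base, **dict(zip(free, best.x)))
    return FitResult(spec, params, float(best.fun), data.n_trials, len(free),
                     bic(float(best.fun), len(free), data.n_trials),
                     bool(converged), float(spread))


def compare_models(sessions, specs, cfg: FitConfig | None = None) -> pd.DataFrame:
    """Fit every spec and tabulate BIC, dBIC from the best, and ln(dBIC).

    Columns mirror the model-comparison figure layout: family, n_free, nll,
    bic, dbic, ln_dbic, best_flag.  A failed fit marks its row; comparison
    proceeds over the rest.
    """
    if len(specs) < 2:
        raise ValueError("need at least two specs to compare")
    data = sessions if isinstance(sessions, SessionArrays) else pack_sessions(sessions)
    rows = []
    for spec in specs:
        try:
            fit = fit_mle(data, spec, cfg)
            rows.append({"family": spec.family, "n_free": fit.n_free,
                         "nll": fit.nll, "bic": fit.bic,
                         "converged": fit.converged, "error": ""})
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("fit failed for %s: %s", spec.family, exc)
            rows.append({"family": spec.family, "n_free": np.nan, "nll": np.nan,
                         "bic": np.nan, "converged": False, "error": str(exc)})
    table = pd.DataFrame(rows)
    best_bic = table["bic"].min()
    table["dbic"] = table["bic"] - best_bic
    with np.errstate(divide="ignore"):
        table["ln_dbic"] = np.log(table["dbic"].to_numpy())
    table["best_flag"] = table["bic"] == best_bic
    return table


def baseline_binding(baseline: FitResult) -> dict[str, float]:
    """Extract the frozen saline parameter values for a K-model spec."""
    if baseline.spec.family not in ("DF", "DF-R"):
        raise ValueError("baseline must be a differential-forgetting fit")
    if not baseline.converged:
        raise ValueError("baseline fit did not converge")
    b = {name: getattr(baseline.params, name) for name in BASELINE_PARAM_NAMES}
    if baseline.spec.family == "DF-R":
        b["delta_neutral"] = 0.0
    return b


def fit_kmodel(ketamine_sessions, baseline: FitResult, family: str,
               cfg: FitConfig | None = None) -> FitResult:
    """Two-stage fit: freeze the saline baseline, optimise the K-model's
    deviation parameters on the ketamine sessions."""
    if family not in FAMILY_FREE or not family.startswith("K"):
        raise ValueError(f"not a K-model family: {family!r}")
    spec = ModelSpec(family, baseline=baseline_binding(baseline))
    return fit_mle(ketamine_sessions, spec, cfg)
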