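"""Descriptive analyses of outcome-dependent choice behavior.

The workhorse is a lagged-outcome logistic regression: the probability of
choosing the right target is modelled from signed regressors encoding, for
each of the last five trials, which outcome (gain / neutral / loss, plus the
juice exchange) occurred and which side was chosen,

    logit P_t(R) = sum_i b_i^G G(t-i) + b_i^N N(t-i) + b_i^L L(t-i)
                   + b_i^R R(t-i),        i = 1..5,

with G(t-i) = +1 (-1) when trial t-i ended in a gain after a right (left)
choice and 0 otherwise, and likewise for the other outcome classes.  A
positive coefficient means the outcome increased the tendency to repeat the
same side.  The decay of these coefficients over lags is summarised with an
exponential curve whose amplitude and time constant may shift between saline
and drug sessions,

    Y_i = (b0s + b0k*Ik) * exp(-(i-1) / (b1s + b1k*Ik)),

with the indicator Ik = 1 for drug sessions.  Further analyses contrast
coefficient sets between conditions, trace the lag-1 modulation over time
from injection against shuffled-null bands, and tabulate choice-switch
probability after loss as a function of token asset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

log = logging.getLogger(__name__)

REGRESSOR_OUTCOMES = ("G", "N", "L", "R")
_OUTCOME_TO_REG = {"gain": "G", "neutral": "N", "loss": "L"}


def build_history_design(trials: pd.DataFrame, n_lags: int = 5) -> pd.DataFrame:
    """Build the lagged signed-outcome design, one row per predictable trial.

    Rows are emitted only for trials with at least ``n_lags`` predecessors in
    the same session (lags never cross session boundaries).  Columns ``G_i``,
    ``N_i``, ``L_i``, ``R_i`` hold the signed regressors for lag ``i``;
    ``y`` is 1 for a right choice; session metadata is carried through.
    """
    frames = []
    for sid, sess in trials.groupby("session_id", sort=False):
        if len(sess) <= n_lags:
            log.warning("session %s has %d trials <= n_lags=%d; no design rows",
                        sid, len(sess), n_lags)
            continue
        sess = sess.sort_values("trial_index")
        sign = np.where(sess["animal_choice"].to_numpy() == "R", 1.0, -1.0)
        cols = {}
        for i in range(1, n_lags + 1):
            lag_sign = sign[n_lags - i:len(sess) - i]
            lag_out = sess["outcome_class"].to_numpy()[n_lags - i:len(sess) - i]
            lag_juice = sess["juice_delivered"].to_numpy()[n_lags - i:len(sess) - i]
            for reg in ("G", "N", "L"):
                cols[f"{reg}_{i}"] = np.where(
                    [_OUTCOME_TO_REG[o] == reg for o in lag_out], lag_sign, 0.0)
            cols[f"R_{i}"] = np.where(np.asarray(lag_juice, dtype=bool), lag_sign, 0.0)
        design = pd.DataFrame(cols)
        design["y"] = (sess["animal_choice"].to_numpy()[n_lags:] == "R").astype(float)
        for meta in ("session_id", "animal_id", "condition", "route",
                     "time_from_injection", "trial_index"):
            if meta in sess.columns:
                design[meta] = sess[meta].to_numpy()[n_lags:]
        frames.append(design)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def design_columns(n_lags: int = 5) -> list[str]:
    return [f"{reg}_{i}" for reg in REGRESSOR_OUTCOMES for i in range(1, n_lags + 1)]


@dataclass
class CoefficientSet:
    """Fitted lagged-outcome coefficients with standard errors.

    ``table`` is indexed by (outcome, lag) with columns estimate / se.
    """

    table: pd.DataFrame
    condition: str = ""
    route: str = ""
    intercept: float = 0.0
    intercept_se: float = np.nan
    n_rows: int = 0
    n_lags: int = 5

    def estimate(self, outcome: str, lag: int) -> float:
        return float(self.table.loc[(outcome, lag), "estimate"])

    def se(self, outcome: str, lag: int) -> float:
        return float(self.table.loc[(outcome, lag), "se"])


def fit_choice_logit(design: pd.DataFrame, *, condition: str = "",
                     route: str = "", n_lags: int = 5,
                     add_intercept: bool = True) -> CoefficientSet:
    """ML logistic fit of choice on the lagged signed-outcome regressors."""
    cols = design_columns(n_lags)
    if len(design) < 200:
        log.warning("only %d design rows; coefficient estimates will be noisy",
                    len(design))
    X = design[cols].to_numpy()
    nonzero = np.abs(X).sum(axis=0) > 0
    if not nonzero.all():
        dead = [c for c, ok in zip(cols, nonzero) if not ok]
        raise ValueError(f"all-zero regressor columns: {dead}")
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
    model = sm.Logit(design["y"].to_numpy(), X)
    try:
        res = model.fit(disp=0, maxiter=200)
    except Exception as exc:
        raise RuntimeError(f"logistic fit failed ({exc}); check for separation "
                           f"or collinearity in {cols}") from exc
    off = 1 if add_intercept else 0
    idx = pd.MultiIndex.from_tuples(
        [(reg, i) for reg in REGRESSOR_OUTCOMES for i in range(1, n_lags + 1)],
        names=["outcome", "lag"])
    table = pd.DataFrame({"estimate": res.params[off:], "se": res.bse[off:]},
                         index=idx)
    return CoefficientSet(table=table, condition=condition, route=route,
                          intercept=float(res.params[0]) if add_intercept else 0.0,
                          intercept_se=float(res.bse[0]) if add_intercept else np.nan,
                          n_rows=len(design), n_lags=n_lags)


def contrast_conditions(saline: CoefficientSet,
                        ketamine: CoefficientSet) -> pd.DataFrame:
    """Per-(outcome, lag) Wald contrast of two coefficient sets.

    Returns difference (ketamine - saline), pooled SE, z statistic, two-sided
    p value, and a significance flag at p < 0.05.
    """
    if not saline.table.index.equals(ketamine.table.index):
        raise ValueError("coefficient layouts do not match")
    diff = ketamine.table["estimate"] - saline.table["estimate"]
    pooled_se = np.sqrt(saline.table["se"] ** 2 + ketamine.table["se"] ** 2)
    z = diff / pooled_se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"diff": diff, "pooled_se": pooled_se, "z": z,
                         "p": p, "significant": p < 0.05})


@dataclass
class ExpDecayFit:
    outcome: str
    b0s: float
    b0k: float
    b1s: float
    b1k: float
    residual_norm: float
    converged: bool


def exp_decay(lag, ik, b0s: float, b0k: float, b1s: float, b1k: float):
    """Evaluate the condition-modulated exponential decay curve at trial lag
    ``lag`` (1-based) with drug indicator ``ik`` in {0, 1}."""
    lag = np.asarray(lag, dtype=float)
    ik = np.asarray(ik, dtype=float)
    return (b0s + b0k * ik) * np.exp(-(lag - 1.0) / (b1s + b1k * ik))


def fit_exponential_decay(saline: CoefficientSet, ketamine: CoefficientSet,
                          outcome: str) -> ExpDecayFit:
    """Nonlinear least squares of the decay curve to one outcome's lagged
    coefficients from both conditions.

    Time constants are optimised on a positive box for each condition branch
    (the ketamine modulation ``b1k`` is reported as the difference of branch
    time constants), which keeps both branches of the curve well defined.
    """
    if outcome not in ("G", "N", "L", "R"):
        raise ValueError(f"unknown outcome label: {outcome!r}")
    n_lags = saline.n_lags
    lags = np.arange(1, n_lags + 1, dtype=float)
    y = np.concatenate([[saline.estimate(outcome, i) for i in lags.astype(int)],
                        [ketamine.estimate(outcome, i) for i in lags.astype(int)]])
    lag_all = np.concatenate([lags, lags])
    ik = np.concatenate([np.zeros(n_lags), np.ones(n_lags)])

    def resid(theta):
        b0s, b0k, ts, tk = theta
        b1 = np.where(ik > 0, tk, ts)
        return (b0s + b0k * ik) * np.exp(-(lag_all - 1.0) / b1) - y

    t0 = 1.5
    x0 = np.array([y[0], y[n_lags] - y[0], t0, t0])
    lo = np.array([-50.0, -50.0, 1e-2, 1e-2])
    hi = np.array([50.0, 50.0, 1e3, 1e3])
    res = optimize.least_squares(resid, np.clip(x0, lo, hi), bounds=(lo, hi),
                                 xtol=1e-12, ftol=1e-12, gtol=1e-12)
    b0s, b0k, ts, tk = res.x
    return ExpDecayFit(outcome=outcome, b0s=float(b0s), b0k=float(b0k),
                       b1s=float(ts), b1k=float(tk - ts),
                       residual_norm=float(np.linalg.norm(res.fun)),
                       converged=bool(res.success))


# ---------------------------------------------------------------------------
# time-resolved modulation with shuffled nulls
# ---------------------------------------------------------------------------

def _lag1_coefs(design: pd.DataFrame, n_lags: int):
    """Lag-1 G/N/L coefficients of a logistic fit, or None on failure."""
    try:
        cs = fit_choice_logit(design, n_lags=n_lags)
    except (ValueError, RuntimeError):
        return None
    return np.array([cs.estimate("G", 1), cs.estimate("N", 1), cs.estimate("L", 1)])


def time_resolved_modulation(sessions: pd.DataFrame, *,
                             bin_edges_min=None, n_shuffles: int = 1000,
                             seed: int = 0, n_lags: int = 5,
                             min_rows: int = 200) -> pd.DataFrame:
    """Ketamine-minus-saline lag-1 coefficient differences per time bin, with
    shuffled-null bands.

    Within each bin of time-from-injection, the lagged-outcome logistic model
    is fit separately per condition and the lag-1 coefficient difference is
    reported per outcome.  The null distribution is obtained by randomly
    reassigning the condition label across sessions ``n_shuffles`` times;
    the output carries both the null standard error (``se_null``, the band
    dotted-line bands of the original analysis are built from) and the
    central 95% percentile band.  Bins with fewer
    than ``min_rows`` rows in either condition are skipped.
    """
    if bin_edges_min is None:
        bin_edges_min = np.arange(-20.0, 90.0, 10.0)
    design = build_history_design(sessions, n_lags=n_lags)
    if design.empty:
        raise ValueError("no design rows; sessions too short?")
    design["time_min"] = design["time_from_injection"] / 60.0
    sess_ids = design["session_id"].unique()
    true_cond = design.groupby("session_id")["condition"].first()
    rng = np.random.default_rng(seed)
    rows = []
    for lo, hi in zip(bin_edges_min[:-1], bin_edges_min[1:]):
        sub = design[(design["time_min"] >= lo) & (design["time_min"] < hi)]
        sal = sub[sub["condition"] == "saline"]
        ket = sub[sub["condition"] == "ketamine"]
        if len(sal) < min_rows or len(ket) < min_rows:
            log.info("bin [%s, %s) skipped: %d saline / %d ketamine rows",
                     lo, hi, len(sal), len(ket))
            continue
        c_sal = _lag1_coefs(sal, n_lags)
        c_ket = _lag1_coefs(ket, n_lags)
        if c_sal is None or c_ket is None:
            log.info("bin [%s, %s) skipped: fit failure", lo, hi)
            continue
        diffs = c_ket - c_sal
        null = []
        labels = true_cond.loc[sess_ids].to_numpy()
        for _ in range(n_shuffles):
            perm = rng.permutation(labels)
            mapping = dict(zip(sess_ids, perm))
            cond_perm = sub["session_id"].map(mapping)
            c0 = _lag1_coefs(sub[cond_perm == "saline"], n_lags)
            c1 = _lag1_coefs(sub[cond_perm == "ketamine"], n_lags)
            if c0 is not None and c1 is not None:
                null.append(c1 - c0)
        null = np.array(null) if null else np.empty((0, 3))
        for j, outcome in enumerate(("G", "N", "L")):
            row = {"bin_lo_min": lo, "bin_hi_min": hi, "outcome": outcome,
                   "diff": diffs[j], "n_saline": len(sal), "n_ketamine": len(ket),
                   "n_null": len(null)}
            if len(null):
                row["null_mean"] = float(null[:, j].mean())
                row["se_null"] = float(null[:, j].std(ddof=1))
                row["band_lo"] = float(np.percentile(null[:, j], 2.5))
                row["band_hi"] = float(np.percentile(null[:, j], 97.5))
            else:
                row["null_mean"] = row["se_null"] = np.nan
                row["band_lo"] = row["band_hi"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# switch probability by asset
# ---------------------------------------------------------------------------

DEFAULT_ASSET_BINS = ((0, 1), (2, 2), (3, 3), (4, 4))


def switch_prob_by_asset(trials: pd.DataFrame, *, outcome_filter: str = "loss",
                         asset_bins=DEFAULT_ASSET_BINS) -> dict:
    """P(switch | previous outcome) by token-asset bin and condition.

    Considers trials whose previous trial (same session) ended in
    ``outcome_filter``; a switch means choosing the other side than on that
    previous trial.  Returns per-bin switch probabilities per condition, the
    ketamine-minus-saline differences, and a condition-by-asset interaction
    test (logistic regression over the filtered trials).
    """
    parts = []
    for _, sess in trials.groupby("session_id", sort=False):
        sess = sess.sort_values("trial_index")
        prev_out = sess["outcome_class"].shift(1)
        prev_choice = sess["animal_choice"].shift(1)
        keep = prev_out == outcome_filter
        if keep.any():
            parts.append(pd.DataFrame({
                "switch": (sess["animal_choice"] != prev_choice)[keep].astype(float),
                "asset": sess["asset_pre"][keep].astype(int),
                "condition": sess["condition"][keep],
            }))
    if not parts:
        raise ValueError(f"no trials follow a {outcome_filter!r} outcome")
    df = pd.concat(parts, ignore_index=True)

    rows = []
    for lo, hi in asset_bins:
        label = f"{lo}" if lo == hi else f"{lo}-{hi}"
        sel = (df["asset"] >= lo) & (df["asset"] <= hi)
        row = {"asset_bin": label, "bin_lo": lo, "bin_hi": hi}
        for cond in ("saline", "ketamine"):
            grp = df[sel & (df["condition"] == cond)]
            row[f"n_{cond}"] = len(grp)
            row[f"p_switch_{cond}"] = grp["switch"].mean() if len(grp) else np.nan
        row["diff"] = row["p_switch_ketamine"] - row["p_switch_saline"]
        rows.append(row)
    table = pd.DataFrame(rows)

    # condition x asset interaction on the trial level
    trend = {"interaction_coef": np.nan, "interaction_z": np.nan,
             "interaction_p": np.nan}
    if df["condition"].nunique() == 2 and df["asset"].nunique() > 1:
        is_ket = (df["condition"] == "ketamine").astype(float).to_numpy()
        asset = df["asset"].to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([is_ket, asset, is_ket * asset]))
        try:
            res = sm.Logit(df["switch"].to_numpy(), X).fit(disp=0, maxiter=200)
            trend = {"interaction_coef": float(res.params[3]),
                     "interaction_z": float(res.tvalues[3]),
                     "interaction_p": float(res.pvalues[3])}
        except Exception as exc:
            log.warning("interaction test failed: %s", exc)
    return {"table": table, "trend": trend, "n_trials": len(df)}
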