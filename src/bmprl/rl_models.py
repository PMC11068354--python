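"""Forgetting Q-learning model family for trial-by-trial choice in the token game.

Baseline families (fit to saline behavior)
------------------------------------------
Every family updates a pair of action values Q(R), Q(L) once per trial and
maps their difference through a logistic choice rule P(R) = 1/(1+exp(-beta*X)).

* ``Q``      standard Q-learning: chosen value moves toward the outcome
             R in {+1, 0, -1} with learning rate alpha_L (forgetting rate
             1 - alpha_L); beta is free.
* ``QSE``    subjective outcome evaluation: the product of learning rate and
             outcome value is consolidated into one free update Delta per
             outcome class (Delta_G, Delta_N, Delta_L); chosen value only.
             ``QSE-R`` fixes Delta_N = 0 (neutral as reference point).
* ``DF``     differential forgetting: chosen and unchosen values decay at
             separate rates alpha_F-C and alpha_F-UC; the chosen value also
             receives Delta.  ``DF-R`` fixes Delta_N = 0.
* ``NDF``    one common forgetting rate for both values.  ``NDF-R`` ditto.
* ``DF-A`` / ``NDF-A``   asset-gated outcome evaluation: the chosen update is
             lambda * asset * R, scaling the outcome's impact by the number of
             tokens owned at decision time.

For every family except standard ``Q``, beta is fixed at 1 (free Delta's and a
free beta are jointly unidentifiable).

Ketamine-modulation variants (K1-K11)
-------------------------------------
Each K-model is the DF model with its saline maximum-likelihood parameters
(the *baseline binding*: alpha_F-C^S, alpha_F-UC^S, Delta^S triple) frozen,
plus a small set of free deviation parameters encoding one hypothesis:

1-4   value: additive shifts k (common / separate) to the non-gain or all
      Delta's, up to fully free Delta^K triple (K4);
5     memory: free forgetting-rate pair;
6-7   perseveration: X = (1-eps)*(Q_R - Q_L) + eps*I_{t-1} with the signed
      previous-choice indicator I (+1 right, -1 left); K7 = K4 + K6;
8-9   temporal credit assignment: backward misassignment pairs the previous
      outcome's Delta^S with choices 2-4 trials back (weights omega_1..3);
      forward spread pairs the previous choice with Delta^S of outcomes 2-4
      trials back;
10    statistical learning: X gains omega_1 * 1(|rFreq| >= tau) * rFreq *
      avgDelta, with rFreq the difference of exponentially decayed choice
      frequencies (decay rho) and avgDelta a decayed outcome-update average
      (decay phi);
11    motivation: asset-gated chosen update lambda * asset * Delta^S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bmp_task
from .records import OUTCOMES, SIDES, TrialRecord, records_to_frame

P_CLIP = 1e-12  # likelihood floor for a single choice probability

BASELINE_FAMILIES = ("Q", "QSE", "QSE-R", "DF", "DF-R", "NDF", "NDF-R", "DF-A", "NDF-A")
K_FAMILIES = tuple(f"K{i}" for i in range(1, 12))

#: free parameters per family, in canonical order
FAMILY_FREE: dict[str, tuple[str, ...]] = {
    "Q": ("alpha_L", "beta"),
    "QSE": ("alpha_F", "delta_gain", "delta_neutral", "delta_loss"),
    "QSE-R": ("alpha_F", "delta_gain", "delta_loss"),
    "DF": ("alpha_F_C", "alpha_F_UC", "delta_gain", "delta_neutral", "delta_loss"),
    "DF-R": ("alpha_F_C", "alpha_F_UC", "delta_gain", "delta_loss"),
    "NDF": ("alpha_F", "delta_gain", "delta_neutral", "delta_loss"),
    "NDF-R": ("alpha_F", "delta_gain", "delta_loss"),
    "DF-A": ("alpha_F_C", "alpha_F_UC", "lambda_"),
    "NDF-A": ("alpha_F", "lambda_"),
    "K1": ("k",),
    "K2": ("k1", "k2"),
    "K3": ("k1", "k2"),
    "K4": ("delta_gain", "delta_neutral", "delta_loss"),
    "K5": ("alpha_F_C", "alpha_F_UC"),
    "K6": ("epsilon",),
    "K7": ("delta_gain", "delta_neutral", "delta_loss", "epsilon"),
    "K8": ("omega1", "omega2", "omega3"),
    "K9": ("omega1", "omega2", "omega3"),
    "K10": ("omega1", "rho", "tau", "phi"),
    "K11": ("lambda_",),
}

BASELINE_PARAM_NAMES = ("alpha_F_C", "alpha_F_UC", "delta_gain", "delta_neutral",
                        "delta_loss")


@dataclass
class ParamSet:
    """Union of all model parameters; a ModelSpec decides which are read."""

    alpha_F: float = 0.0
    alpha_F_C: float = 0.0
    alpha_F_UC: float = 0.0
    alpha_L: float = 0.0
    delta_gain: float = 0.0
    delta_neutral: float = 0.0
    delta_loss: float = 0.0
    beta: float = 1.0
    lambda_: float = 0.0
    epsilon: float = 0.0
    omega1: float = 0.0
    omega2: float = 0.0
    omega3: float = 0.0
    rho: float = 0.0
    tau: float = 0.0
    phi: float = 0.0
    k: float = 0.0
    k1: float = 0.0
    k2: float = 0.0

    def validate(self) -> None:
        for name in ("alpha_F", "alpha_F_C", "alpha_F_UC", "alpha_L",
                     "epsilon", "rho", "phi"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for name in ("delta_gain", "delta_neutral", "delta_loss", "lambda_",
                     "omega1", "omega2", "omega3", "k", "k1", "k2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} is not finite")


@dataclass
class ModelSpec:
    """A model family plus, for K-models, the frozen saline baseline values."""

    family: str
    baseline: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILY_FREE:
            raise ValueError(f"unknown model family: {self.family!r}")
        if self.is_kmodel:
            if self.baseline is None:
                raise ValueError(f"{self.family} requires a saline baseline binding")
            missing = set(BASELINE_PARAM_NAMES) - set(self.baseline)
            if missing:
                raise ValueError(f"baseline binding missing {sorted(missing)}")

    @property
    def is_kmodel(self) -> bool:
        return self.family in K_FAMILIES

    @property
    def free_params(self) -> tuple[str, ...]:
        return FAMILY_FREE[self.family]


@dataclass
class ValueState:
    """Per-trial latent state: action values plus the auxiliary traces read by
    the perseveration / credit-assignment / statistical-learning variants.

    ``recent_choices`` and ``recent_deltas`` are newest-first buffers of the
    signed choice indicators I (+1/-1) and saline-valued outcome updates
    Delta^S of the last four trials; missing history reads as 0.
    """

    q_right: float = 0.0
    q_left: float = 0.0
    freq_right: float = 0.0
    freq_left: float = 0.0
    avg_delta: float = 0.0
    recent_choices: tuple[float, ...] = ()
    recent_deltas: tuple[float, ...] = ()

    def buffer(self, which: str, lag: int) -> float:
        """Signed choice indicator / Delta^S of the trial ``lag`` back (1 = previous)."""
        buf = self.recent_choices if which == "choice" else self.recent_deltas
        return buf[lag - 1] if lag <= len(buf) else 0.0


def _outcome_index(outcome_class: str) -> int:
    try:
        return OUTCOMES.index(outcome_class)
    except ValueError:
        raise ValueError(f"unknown outcome class: {outcome_class!r}") from None


def _update_rule(spec: ModelSpec, params: ParamSet):
    """Resolve the family to (a_chosen, a_unchosen, deltas[3], asset_gated).

    ``deltas`` is the per-outcome chosen-value update (gain, neutral, loss);
    when ``asset_gated`` it is additionally multiplied by the decision-time
    asset.
    """
    f, p = spec.family, params
    if f == "Q":
        return 1.0 - p.alpha_L, 1.0, (p.alpha_L, 0.0, -p.alpha_L), False
    if f in ("QSE", "QSE-R"):
        dn = 0.0 if f.endswith("-R") else p.delta_neutral
        return p.alpha_F, 1.0, (p.delta_gain, dn, p.delta_loss), False
    if f in ("DF", "DF-R"):
        dn = 0.0 if f.endswith("-R") else p.delta_neutral
        return p.alpha_F_C, p.alpha_F_UC, (p.delta_gain, dn, p.delta_loss), False
    if f in ("NDF", "NDF-R"):
        dn = 0.0 if f.endswith("-R") else p.delta_neutral
        return p.alpha_F, p.alpha_F, (p.delta_gain, dn, p.delta_loss), False
    if f == "DF-A":
        return p.alpha_F_C, p.alpha_F_UC, (p.lambda_, 0.0, -p.lambda_), True
    if f == "NDF-A":
        return p.alpha_F, p.alpha_F, (p.lambda_, 0.0, -p.lambda_), True
    # K-models: start from the frozen saline baseline
    b = spec.baseline
    a_c, a_uc = b["alpha_F_C"], b["alpha_F_UC"]
    dG, dN, dL = b["delta_gain"], b["delta_neutral"], b["delta_loss"]
    if f == "K1":
        return a_c, a_uc, (dG, dN + p.k, dL + p.k), False
    if f == "K2":
        return a_c, a_uc, (dG, dN + p.k1, dL + p.k2), False
    if f == "K3":
        return a_c, a_uc, (dG + p.k1, dN + p.k2, dL + p.k2), False
    if f in ("K4", "K7"):
        return a_c, a_uc, (p.delta_gain, p.delta_neutral, p.delta_loss), False
    if f == "K5":
        return p.alpha_F_C, p.alpha_F_UC, (dG, dN, dL), False
    if f in ("K6", "K8", "K9", "K10"):
        return a_c, a_uc, (dG, dN, dL), False
    if f == "K11":
        return a_c, a_uc, (p.lambda_ * dG, p.lambda_ * dN, p.lambda_ * dL), True
    raise ValueError(f"unknown model family: {f!r}")


def _trace_deltas(spec: ModelSpec, params: ParamSet) -> tuple[float, float, float]:
    """Saline-valued Delta^S per outcome, fed into the auxiliary traces."""
    if spec.baseline is not None:
        b = spec.baseline
        return b["delta_gain"], b["delta_neutral"], b["delta_loss"]
    _, _, deltas, _ = _update_rule(spec, params)
    return deltas


def update_values(state: ValueState, chosen: str, outcome_class: str,
                  asset_pre: int, spec: ModelSpec, params: ParamSet) -> ValueState:
    """Advance action values and auxiliary traces after one observed trial."""
    if chosen not in SIDES:
        raise ValueError(f"unknown side: {chosen!r}")
    a_c, a_uc, deltas, gated = _update_rule(spec, params)
    j = _outcome_index(outcome_class)
    delta = deltas[j] * (asset_pre if gated else 1.0)
    if chosen == "R":
        q_r = a_c * state.q_right + delta
        q_l = a_uc * state.q_left
    else:
        q_l = a_c * state.q_left + delta
        q_r = a_uc * state.q_right
    ds = _trace_deltas(spec, params)[j]
    ind = 1.0 if chosen == "R" else -1.0
    return ValueState(
        q_right=q_r,
        q_left=q_l,
        freq_right=params.rho * state.freq_right + (chosen == "R"),
        freq_left=params.rho * state.freq_left + (chosen == "L"),
        avg_delta=params.phi * state.avg_delta + ds,
        recent_choices=(ind, *state.recent_choices)[:4],
        recent_deltas=(ds, *state.recent_deltas)[:4],
    )


def decision_variable(state: ValueState, spec: ModelSpec, params: ParamSet) -> float:
    """The value difference X_t feeding the logistic choice rule, including
    the K-model deviation terms."""
    x = state.q_right - state.q_left
    f, p = spec.family, params
    if f in ("K6", "K7"):
        return (1.0 - p.epsilon) * x + p.epsilon * state.buffer("choice", 1)
    if f == "K8":
        ds1 = state.buffer("delta", 1)
        return x + ds1 * (p.omega1 * state.buffer("choice", 2)
                          + p.omega2 * state.buffer("choice", 3)
                          + p.omega3 * state.buffer("choice", 4))
    if f == "K9":
        ic1 = state.buffer("choice", 1)
        return x + ic1 * (p.omega1 * state.buffer("delta", 2)
                          + p.omega2 * state.buffer("delta", 3)
                          + p.omega3 * state.buffer("delta", 4))
    if f == "K10":
        rfreq = state.freq_right - state.freq_left
        if abs(rfreq) >= p.tau:
            x = x + p.omega1 * rfreq * state.avg_delta
        return x
    return x


def choice_probability(x: float, beta: float) -> float:
    """Logistic choice rule: probability of choosing the right target."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = min(max(beta * x, -700.0), 700.0)
    return 1.0 / (1.0 + math.exp(-z))


def session_nll(trials, spec: ModelSpec, params: ParamSet) -> float:
    """Negative log-likelihood of one session's observed choices.

    Reference trial-by-trial implementation; the fitting module uses the
    vectorised :func:`pooled_nll`, which is tested against this path.
    Accepts a sequence of TrialRecords or a session DataFrame.
    """
    params.validate()
    if isinstance(trials, pd.DataFrame):
        rows = zip(trials["animal_choice"], trials["outcome_class"], trials["asset_pre"])
    else:
        rows = ((t.animal_choice, t.outcome_class, t.asset_pre) for t in trials)
    state = ValueState()
    nll = 0.0
    max_term = -math.log(P_CLIP)
    for choice, outcome, asset_pre in rows:
        x = decision_variable(state, spec, params)
        # -log P(observed) via the stable softplus form, floored at P_CLIP
        z = min(max(params.beta * x, -700.0), 700.0)
        a = z if choice != "R" else -z
        term = max(a, 0.0) + math.log1p(math.exp(-abs(a)))
        nll += min(term, max_term)
        state = update_values(state, choice, outcome, int(asset_pre), spec, params)
    return nll


# ---------------------------------------------------------------------------
# vectorised likelihood over a stack of sessions (used by the fitter)
# ---------------------------------------------------------------------------

@dataclass
class SessionArrays:
    """Sessions packed into (n_sessions, max_len) arrays, padded with -1."""

    choice: np.ndarray   # int8: 0=L, 1=R, -1=pad
    outcome: np.ndarray  # int8: 0=gain, 1=neutral, 2=loss, -1=pad
    asset: np.ndarray    # int16: asset at decision time, 0 on pad
    n_trials: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_trials = int((self.choice >= 0).sum())


def pack_sessions(sessions) -> SessionArrays:
    """Pack session DataFrames (or one frame with a session_id column) into
    padded arrays for the vectorised likelihood."""
    if isinstance(sessions, pd.DataFrame):
        sessions = [g for _, g in sessions.groupby("session_id", sort=True)]
    lengths = [len(s) for s in sessions]
    n, t_max = len(sessions), max(lengths)
    choice = np.full((n, t_max), -1, dtype=np.int8)
    outcome = np.full((n, t_max), -1, dtype=np.int8)
    asset = np.zeros((n, t_max), dtype=np.int16)
    for i, s in enumerate(sessions):
        m = lengths[i]
        choice[i, :m] = (s["animal_choice"].to_numpy() == "R").astype(np.int8)
        outcome[i, :m] = pd.Categorical(
            s["outcome_class"], categories=list(OUTCOMES)).codes.astype(np.int8)
        asset[i, :m] = s["asset_pre"].to_numpy()
    if (outcome[choice >= 0] < 0).any():
        raise ValueError("unknown outcome class in session data")
    return SessionArrays(choice, outcome, asset)


def pooled_nll(data: SessionArrays, spec: ModelSpec, params: ParamSet) -> float:
    """Summed negative log-likelihood over all packed sessions.

    Runs one pass over trial index, vectorised across sessions; each session's
    value state starts fresh at zero.  Matches :func:`session_nll` summed over
    sessions to ~1e-12.
    """
    params.validate()
    a_c, a_uc, deltas, gated = _update_rule(spec, params)
    deltas = np.asarray(deltas + (0.0,))          # index -1 (pad) -> 0
    ds_base = np.asarray(_trace_deltas(spec, params) + (0.0,))
    f, p = spec.family, params
    needs_traces = f in ("K6", "K7", "K8", "K9", "K10")
    n, t_max = data.choice.shape
    q_r = np.zeros(n)
    q_l = np.zeros(n)
    ic = np.zeros((4, n))   # signed previous-choice indicators, lag 1..4
    ds = np.zeros((4, n))   # Delta^S of previous outcomes, lag 1..4
    f_r = np.zeros(n)
    f_l = np.zeros(n)
    avg_d = np.zeros(n)
    xs = np.empty((n, t_max))
    for t in range(t_max):
        x = q_r - q_l
        if f in ("K6", "K7"):
            x = (1.0 - p.epsilon) * x + p.epsilon * ic[0]
        elif f == "K8":
            x = x + ds[0] * (p.omega1 * ic[1] + p.omega2 * ic[2] + p.omega3 * ic[3])
        elif f == "K9":
            x = x + ic[0] * (p.omega1 * ds[1] + p.omega2 * ds[2] + p.omega3 * ds[3])
        elif f == "K10":
            rfreq = f_r - f_l
            x = x + p.omega1 * (np.abs(rfreq) >= p.tau) * rfreq * avg_d
        xs[:, t] = x
        ch = data.choice[:, t]
        valid = ch >= 0
        out = data.outcome[:, t]
        delta = deltas[out]
        if gated:
            delta = delta * data.asset[:, t]
        is_r = ch == 1
        is_l = ch == 0
        q_r = np.where(is_r, a_c * q_r + delta, np.where(valid, a_uc * q_r, q_r))
        q_l = np.where(is_l, a_c * q_l + delta, np.where(valid, a_uc * q_l, q_l))
        if needs_traces:
            ind = np.where(is_r, 1.0, np.where(is_l, -1.0, 0.0))
            ic[1:] = ic[:-1]
            ic[0] = ind
            ds[1:] = ds[:-1]
            ds[0] = ds_base[out] * valid
            f_r = p.rho * f_r + is_r
            f_l = p.rho * f_l + is_l
            avg_d = p.phi * avg_d + ds_base[out] * valid
    # log-likelihood in one vectorised pass: -log P(observed) with the same
    # probability floor as session_nll
    sign = np.where(data.choice == 1, 1.0, -1.0)
    z_obs = sign * np.clip(p.beta * xs, -700.0, 700.0)
    term = np.minimum(np.logaddexp(0.0, -z_obs), -math.log(P_CLIP))
    return float(term[data.choice >= 0].sum())


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_agent(task: bmp_task.TaskConfig, opponent: bmp_task.OpponentConfig,
                   spec: ModelSpec, params: ParamSet, n_trials: int,
                   rng: np.random.Generator | int, *,
                   schedule=None,
                   session_id: str = "sim", animal_id: str = "sim",
                   condition: str = "saline", route: str = "none",
                   time0_s: float = 0.0, trial_period_s: float = 8.0) -> pd.DataFrame:
    """Forward-simulate an agent in the BMP environment.

    The agent samples each choice from the model's choice probability, the
    opponent responds per its configuration, and every trial-level observable
    is recorded.  ``schedule(trial_index, time_s) -> (spec, params)`` may remap
    the model per trial (used to switch parameters inside a drug-effect time
    window); the value state carries across the switch.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    params.validate()
    opp = bmp_task.Opponent(opponent)
    block = bmp_task.BlockState(risky_side=SIDES[rng.integers(2)])
    lo, hi = task.free_tokens_range
    asset = int(rng.integers(lo, hi + 1))
    state = ValueState()
    recs = []
    for t in range(1, n_trials + 1):
        time_s = time0_s + (t - 1) * trial_period_s
        sp, pa = (spec, params) if schedule is None else schedule(t, time_s)
        x = decision_variable(state, sp, pa)
        p_r = choice_probability(x, pa.beta)
        choice = "R" if rng.random() < p_r else "L"
        computer = opp.choose(rng)
        event = bmp_task.resolve_outcome(choice, computer, block, task, rng)
        asset_post, juice, _ = bmp_task.apply_tokens(asset, event, task, rng)
        recs.append(TrialRecord(
            session_id=session_id, animal_id=animal_id, condition=condition,
            route=route, trial_index=t, time_from_injection=time_s,
            risky_side=block.risky_side, animal_choice=choice,
            computer_choice=computer, outcome_class=event.outcome_class,
            token_delta=event.token_delta, asset_pre=asset,
            asset_post=asset_post, juice_delivered=juice))
        opp.observe(choice, event.outcome_class)
        state = update_values(state, choice, event.outcome_class, asset, sp, pa)
        asset = asset_post
        block.trials_in_block += 1
        block = bmp_task.maybe_switch_block(block, task, rng)
    return records_to_frame(recs)
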