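"""Synthetic behavioral studies: session generation, I/O, recovery experiments.

No raw behavioral sessions are publicly available for this task, so analyses
are exercised on synthetic studies whose generating parameters are the
published per-animal maximum-likelihood estimates: saline behavior from the
differential-forgetting (DF) model and ketamine behavior from K-model 4
(outcome-specific Delta modulation).  Three synthetic animal profiles mirror
the three monkeys (P, Y, B), including their payoff magnitudes (one token
gained / two lost for P; two gained / one lost for Y and B) and session
counts.  Ketamine sessions apply the ketamine parameters only inside a
drug-effect time window (0-60 min post injection by default) and saline
parameters outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import fitting, rl_models
from .bmp_task import OpponentConfig, TaskConfig
from .records import COLUMNS

log = logging.getLogger(__name__)

#: published saline DF estimates: (alpha_F-C, alpha_F-UC, dG, dN, dL)
SALINE_PARAMS = {
    "P": (0.72, 0.09, -0.57, -1.30, -2.31),
    "Y": (0.65, 0.20, -0.54, -1.91, -3.15),
    "B": (0.83, 0.19, -1.07, -2.26, -4.12),
}

#: published K-model-4 ketamine estimates: (dG^K, dN^K, dL^K)
KETAMINE_DELTAS = {
    "P": (0.40, 0.11, -0.18),
    "Y": (0.31, -0.18, -0.95),
    "B": (0.18, -0.25, -1.01),
}

#: per-animal token payoff magnitudes and IM session counts (saline, ketamine)
_ANIMAL_TASK = {"P": (1, 2), "Y": (2, 1), "B": (2, 1)}
_SESSION_COUNTS = {"P": (52, 17), "Y": (49, 15), "B": (25, 9)}


def saline_paramset(animal: str) -> rl_models.ParamSet:
    a_c, a_uc, dg, dn, dl = SALINE_PARAMS[animal]
    return rl_models.ParamSet(alpha_F_C=a_c, alpha_F_UC=a_uc, delta_gain=dg,
                              delta_neutral=dn, delta_loss=dl)


def saline_baseline(animal: str) -> dict[str, float]:
    a_c, a_uc, dg, dn, dl = SALINE_PARAMS[animal]
    return {"alpha_F_C": a_c, "alpha_F_UC": a_uc, "delta_gain": dg,
            "delta_neutral": dn, "delta_loss": dl}


def ketamine_spec_params(animal: str):
    """K-model-4 spec (saline baseline frozen) and ketamine Delta ParamSet."""
    dg, dn, dl = KETAMINE_DELTAS[animal]
    spec = rl_models.ModelSpec("K4", baseline=saline_baseline(animal))
    return spec, rl_models.ParamSet(delta_gain=dg, delta_neutral=dn, delta_loss=dl)


@dataclass
class AnimalProfile:
    """One synthetic animal: task payoffs, generating models, session counts."""

    animal_id: str
    task: TaskConfig
    saline_spec: rl_models.ModelSpec
    saline_params: rl_models.ParamSet
    ketamine_spec: rl_models.ModelSpec
    ketamine_params: rl_models.ParamSet
    n_saline: int = 20
    n_ketamine: int = 8
    route: str = "IM"


def monkey_profile(animal: str, *, n_saline: int | None = None,
                   n_ketamine: int | None = None) -> AnimalProfile:
    """Profile mirroring one of the three monkeys, with published parameters."""
    if animal not in SALINE_PARAMS:
        raise ValueError(f"unknown animal profile: {animal!r}")
    gain, loss = _ANIMAL_TASK[animal]
    n_sal, n_ket = _SESSION_COUNTS[animal]
    kspec, kparams = ketamine_spec_params(animal)
    return AnimalProfile(
        animal_id=animal,
        task=TaskConfig(gain_tokens=gain, loss_tokens=loss),
        saline_spec=rl_models.ModelSpec("DF"),
        saline_params=saline_paramset(animal),
        ketamine_spec=kspec,
        ketamine_params=kparams,
        n_saline=n_sal if n_saline is None else n_saline,
        n_ketamine=n_ket if n_ketamine is None else n_ketamine,
    )


@dataclass
class StudyConfig:
    """A full synthetic study: which animals, session sizes, drug window."""

    animals: list[AnimalProfile]
    trials_per_session: int = 700
    trial_period_s: float = 8.0
    session_start_s: float = -1200.0  # first trial 20 min before injection
    drug_window_s: tuple[float, float] = (0.0, 3600.0)
    opponent: OpponentConfig = field(default_factory=OpponentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_session < 1:
            raise ValueError("trials_per_session must be >= 1")
        if self.drug_window_s[1] < self.drug_window_s[0]:
            raise ValueError("drug window must be non-negative")
        for prof in self.animals:
            if prof.n_saline < 1 or prof.n_ketamine < 1:
                raise ValueError("session counts must be >= 1")
            # fail early on unresolved baseline bindings etc.
            prof.saline_params.validate()
            prof.ketamine_params.validate()


def _session_seeds(master_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(master_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def simulate_session(profile: AnimalProfile, cfg: StudyConfig, condition: str,
                     session_id: str, seed: int) -> pd.DataFrame:
    """Simulate one session; ketamine parameters apply only inside the
    drug-effect window."""
    if condition == "saline":
        schedule = None
        spec, params = profile.saline_spec, profile.saline_params
    elif condition == "ketamine":
        lo, hi = cfg.drug_window_s

        def schedule(_t, time_s):
            if lo <= time_s <= hi:
                return profile.ketamine_spec, profile.ketamine_params
            return profile.saline_spec, profile.saline_params

        spec, params = profile.saline_spec, profile.saline_params
    else:
        raise ValueError(f"unknown condition: {condition!r}")
    return rl_models.simulate_agent(
        profile.task, cfg.opponent, spec, params, cfg.trials_per_session,
        np.random.default_rng(seed), schedule=schedule, session_id=session_id,
        animal_id=profile.animal_id, condition=condition, route=profile.route,
        time0_s=cfg.session_start_s, trial_period_s=cfg.trial_period_s)


def generate_study(cfg: StudyConfig) -> dict:
    """Simulate every session of a study.

    Returns ``{"sessions": {animal: {condition: [DataFrame, ...]}},
    "manifest": {...}}``; the manifest records the seed of every session so
    any single session can be regenerated in isolation.
    """
    n_total = sum(p.n_saline + p.n_ketamine for p in cfg.animals)
    seeds = iter(_session_seeds(cfg.seed, n_total))
    sessions: dict = {}
    manifest = {"seed": cfg.seed, "trials_per_session": cfg.trials_per_session,
                "sessions": []}
    for prof in cfg.animals:
        sessions[prof.animal_id] = {"saline": [], "ketamine": []}
        for condition, count in (("saline", prof.n_saline),
                                 ("ketamine", prof.n_ketamine)):
            for i in range(count):
                sid = f"{prof.animal_id}_{condition}_{i:03d}"
                seed = next(seeds)
                frame = simulate_session(prof, cfg, condition, sid, seed)
                sessions[prof.animal_id][condition].append(frame)
                manifest["sessions"].append(
                    {"session_id": sid, "animal": prof.animal_id,
                     "condition": condition, "seed": seed})
    return {"sessions": sessions, "manifest": manifest}


# ---------------------------------------------------------------------------
# study I/O (comma-separated session files + YAML manifest)
# ---------------------------------------------------------------------------

def write_session_csv(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    out["juice_delivered"] = out["juice_delivered"].astype(int)
    out.to_csv(path, index=False)


def read_session_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"session_id": str, "animal_id": str})
    frame["juice_delivered"] = frame["juice_delivered"].astype(bool)
    return frame[COLUMNS]


def save_study(study: dict, directory) -> None:
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for animal, by_cond in study["sessions"].items():
        for condition, frames in by_cond.items():
            for frame in frames:
                sid = frame["session_id"].iloc[0]
                write_session_csv(frame, directory / f"{sid}.csv")
    with open(directory / "manifest.yaml", "w") as fh:
        yaml.safe_dump(study["manifest"], fh, sort_keys=False)


def load_study(directory) -> dict:
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    sessions: dict = {}
    for entry in manifest["sessions"]:
        frame = read_session_csv(directory / f"{entry['session_id']}.csv")
        by_cond = sessions.setdefault(entry["animal"], {"saline": [], "ketamine": []})
        by_cond[entry["condition"]].append(frame)
    return {"sessions": sessions, "manifest": manifest}


def pool_condition(study: dict, animal: str, condition: str) -> pd.DataFrame:
    """All of one animal-condition's sessions as a single trial table."""
    frames = study["sessions"][animal][condition]
    if not frames:
        raise ValueError(f"no {condition} sessions for animal {animal}")
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# parameter-recovery experiments
# ---------------------------------------------------------------------------

def recovery_experiment(spec: rl_models.ModelSpec, true_params: rl_models.ParamSet,
                        n_sessions: int, trials_per_session: int,
                        n_replicates: int, seed: int, *,
                        task: TaskConfig | None = None,
                        opponent: OpponentConfig | None = None,
                        fit_cfg: fitting.FitConfig | None = None) -> dict:
    """Simulate-then-fit replicates and summarise estimator quality.

    Each replicate simulates ``n_sessions`` sessions under ``true_params`` and
    refits ``spec`` (for a K-model the baseline binding inside the spec is
    used both to generate and to fit, mirroring two-stage fitting).  Returns
    per-replicate estimates plus a per-parameter summary with median, bias and
    RMSE against the generating truth.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    task = task or TaskConfig()
    opponent = opponent or OpponentConfig(exploit_mode="uniform")
    fit_cfg = fit_cfg or fitting.FitConfig(n_restarts=6)
    free = spec.free_params
    seeds = _session_seeds(seed, n_replicates * (n_sessions + 1))
    rows = []
    for rep in range(n_replicates):
        rep_seeds = seeds[rep * (n_sessions + 1):(rep + 1) * (n_sessions + 1)]
        frames = [rl_models.simulate_agent(task, opponent, spec, true_params,
                                           trials_per_session, s,
                                           session_id=f"rep{rep}_s{j}")
                  for j, s in enumerate(rep_seeds[:-1])]
        row = {"replicate": rep, "converged": False}
        try:
            fit = fitting.fit_mle(frames, spec,
                                  replace(fit_cfg, seed=rep_seeds[-1]))
            row.update({name: getattr(fit.params, name) for name in free})
            row["nll"] = fit.nll
            row["converged"] = fit.converged
        except Exception as exc:
            log.warning("replicate %d fit failed: %s", rep, exc)
        rows.append(row)
    estimates = pd.DataFrame(rows)
    summary_rows = []
    for name in free:
        truth = getattr(true_params, name)
        est = estimates[name].dropna().to_numpy() if name in estimates else np.array([])
        summary_rows.append({
            "param": name, "truth": truth,
            "median": float(np.median(est)) if est.size else np.nan,
            "bias": float(np.mean(est) - truth) if est.size else np.nan,
            "rmse": float(np.sqrt(np.mean((est - truth) ** 2))) if est.size else np.nan,
            "n_ok": int(est.size),
        })
    return {"estimates": estimates, "summary": pd.DataFrame(summary_rows)}
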