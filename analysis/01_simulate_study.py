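"""Generate the synthetic study that the downstream analyses consume.

Three synthetic animals mirror the three monkeys: their published saline
(differential-forgetting) and ketamine (K-model 4) parameter estimates, and
their payoff magnitudes.  Sessions are played against the exploiting
computer opponent; ketamine parameters apply inside the 0-60 min
post-injection window.  Session counts and lengths here are a reduced
working set so the whole pipeline runs in minutes; the generator itself
scales to arbitrary study sizes.

Writes the session CSVs and manifest to scratch/study/ (bulky, regenerable)
and a small summary table to results/study_summary.csv.
"""

from pathlib import Path

import pandas as pd

from bmprl import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
N_SALINE, N_KETAMINE, TRIALS, SEED = 20, 10, 600, 11


def main() -> None:
    profiles = [sd.monkey_profile(a, n_saline=N_SALINE, n_ketamine=N_KETAMINE)
                for a in ("P", "Y", "B")]
    cfg = sd.StudyConfig(animals=profiles, trials_per_session=TRIALS, seed=SEED)
    study = sd.generate_study(cfg)
    sd.save_study(study, ROOT / "scratch" / "study")

    rows = []
    for animal in ("P", "Y", "B"):
        for condition in ("saline", "ketamine"):
            pooled = sd.pool_condition(study, animal, condition)
            rows.append({
                "animal": animal, "condition": condition,
                "n_sessions": pooled.session_id.nunique(),
                "n_trials": len(pooled),
                "gain_rate": (pooled.outcome_class == "gain").mean(),
                "loss_rate": (pooled.outcome_class == "loss").mean(),
                "juice_rate": pooled.juice_delivered.mean(),
                "p_right": (pooled.animal_choice == "R").mean(),
            })
    summary = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    summary.to_csv(out / "study_summary.csv", index=False)
    print(summary.round(3).to_string(index=False))
    sal = summary[summary.condition == "saline"].gain_rate.mean()
    ket = summary[summary.condition == "ketamine"].gain_rate.mean()
    print(f"\nOverall choice is near-unbiased (P(R) ~ 0.5), but the exploiting "
          f"opponent holds the gain rate well below the 0.5 matching "
          f"equilibrium (saline mean {sal:.2f}) by predicting the strongly "
          f"outcome-driven switching of the saline model; the more "
          f"perseverative ketamine-window behavior is less predictable "
          f"(ketamine mean {ket:.2f}).")


if __name__ == "__main__":
    main()
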