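"""Parameter-recovery experiments around the published estimates.

Simulates behavior from the published per-animal parameter sets (saline DF,
ketamine K-model 4) and refits, reporting the median, bias and RMSE of every
free parameter across replicates.  This is the quantitative core of the
validation: with the original sessions unavailable, recovery of the
generating parameters is the evidence that the fitting machinery measures
what the published analysis measured.  scripts/acceptance.py runs the same
experiments at larger problem sizes.
"""

from pathlib import Path

import pandas as pd

from bmprl import bmp_task, fitting, rl_models, synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
UNIFORM = bmp_task.OpponentConfig(exploit_mode="uniform")
N_SESSIONS, TRIALS, REPLICATES = 16, 1000, 6


def task_for(animal: str) -> bmp_task.TaskConfig:
    gain, loss = {"P": (1, 2), "Y": (2, 1), "B": (2, 1)}[animal]
    return bmp_task.TaskConfig(gain_tokens=gain, loss_tokens=loss)


def main() -> None:
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    tables = []
    for animal in ("P", "Y", "B"):
        for label, (spec, truth) in {
            "DF_saline": (rl_models.ModelSpec("DF"), sd.saline_paramset(animal)),
            "K4_ketamine": sd.ketamine_spec_params(animal),
        }.items():
            report = sd.recovery_experiment(
                spec, truth, n_sessions=N_SESSIONS, trials_per_session=TRIALS,
                n_replicates=REPLICATES, seed=7, task=task_for(animal),
                opponent=UNIFORM, fit_cfg=fitting.FitConfig(n_restarts=4))
            summary = report["summary"].assign(animal=animal, model=label)
            tables.append(summary)
            print(f"{animal} {label}:")
            print(summary[["param", "truth", "median", "bias", "rmse"]]
                  .round(3).to_string(index=False), "\n")
    pd.concat(tables, ignore_index=True).to_csv(
        out / "parameter_recovery.csv", index=False)


if __name__ == "__main__":
    main()
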