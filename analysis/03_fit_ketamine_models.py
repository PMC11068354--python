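"""Two-stage K-model comparison on the ketamine sessions.

For each synthetic animal: fit the differential-forgetting model to the
saline sessions, freeze those estimates as the baseline binding, then fit
all eleven ketamine-modulation variants (value, memory, perseveration,
temporal-credit-assignment, statistical-learning and motivation hypotheses)
to the drug-window trials of the ketamine sessions and compare by BIC.
Because the ketamine trials were generated from K-model 4, the value model
with outcome-specific modulation should be (or tie) the winner.

Writes per-animal comparison tables and a parameter-estimate table mirroring
the published per-animal layout (saline rates and Deltas; ketamine Deltas).
"""

from pathlib import Path

import pandas as pd

from bmprl import fitting, rl_models, synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]


def drug_window_trials(frames, lo=0.0, hi=3600.0):
    """Ketamine sessions restricted to the drug-effect window, so the fitted
    modulation is not diluted by pre/post-window saline behavior."""
    return [g for f in frames
            if len(g := f[(f.time_from_injection >= lo)
                          & (f.time_from_injection <= hi)])]


def main() -> None:
    study = sd.load_study(ROOT / "scratch" / "study")
    cfg = fitting.FitConfig(n_restarts=5, seed=0)
    estimates = []
    for animal in ("P", "Y", "B"):
        saline_fit = fitting.fit_mle(study["sessions"][animal]["saline"],
                                     rl_models.ModelSpec("DF"), cfg)
        binding = fitting.baseline_binding(saline_fit)
        ket = drug_window_trials(study["sessions"][animal]["ketamine"])
        specs = [rl_models.ModelSpec(f, baseline=dict(binding))
                 for f in rl_models.K_FAMILIES]
        table = fitting.compare_models(ket, specs, cfg)
        table.to_csv(ROOT / "results" / f"kmodel_comparison_{animal}.csv",
                     index=False)
        best = table.loc[table.best_flag, "family"].iloc[0]
        print(f"animal {animal}: saline DF nll={saline_fit.nll:.1f}; "
              f"best K-model = {best}")
        print(table[["family", "n_free", "bic", "dbic"]]
              .round(2).to_string(index=False), "\n")

        k4 = fitting.fit_kmodel(ket, saline_fit, "K4", cfg)
        estimates.append({
            "animal": animal,
            "alpha_F_C_saline": saline_fit.params.alpha_F_C,
            "alpha_F_UC_saline": saline_fit.params.alpha_F_UC,
            "delta_gain_saline": saline_fit.params.delta_gain,
            "delta_neutral_saline": saline_fit.params.delta_neutral,
            "delta_loss_saline": saline_fit.params.delta_loss,
            "delta_gain_ketamine": k4.params.delta_gain,
            "delta_neutral_ketamine": k4.params.delta_neutral,
            "delta_loss_ketamine": k4.params.delta_loss,
        })
    est = pd.DataFrame(estimates)
    est.to_csv(ROOT / "results" / "parameter_estimates.csv", index=False)
    print(est.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
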