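"""Baseline model selection on the saline sessions.

Fits the candidate value-update families (standard Q-learning, subjective
outcome evaluation, differential and non-differential forgetting, with and
without the neutral-reference restriction, and asset-gated evaluation) to
each synthetic animal's saline sessions and compares them by BIC.  Because
the saline sessions were generated from the differential-forgetting (DF)
model, DF should win in every animal — the synthetic analogue of the
published model-comparison result.

Reads scratch/study/ (run 01 first); writes one comparison table per animal
to results/.
"""

from pathlib import Path

from bmprl import fitting, rl_models, synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
FAMILIES = ("Q", "QSE", "QSE-R", "DF", "DF-R", "NDF", "NDF-R", "NDF-A")


def main() -> None:
    study = sd.load_study(ROOT / "scratch" / "study")
    cfg = fitting.FitConfig(n_restarts=5, seed=0)
    for animal in ("P", "Y", "B"):
        sessions = study["sessions"][animal]["saline"]
        table = fitting.compare_models(
            sessions, [rl_models.ModelSpec(f) for f in FAMILIES], cfg)
        table.to_csv(ROOT / "results" / f"saline_model_comparison_{animal}.csv",
                     index=False)
        best = table.loc[table.best_flag, "family"].iloc[0]
        print(f"animal {animal}: best family = {best}")
        print(table[["family", "n_free", "nll", "bic", "dbic"]]
              .round(2).to_string(index=False), "\n")


if __name__ == "__main__":
    main()
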