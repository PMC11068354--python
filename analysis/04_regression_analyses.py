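"""Descriptive regression analyses of the synthetic study.

Per animal: the lagged-outcome logistic regression fit separately to saline
and ketamine sessions, the saline-vs-ketamine coefficient contrasts, the
exponential-decay summaries per outcome, the time-resolved lag-1 modulation
with shuffled-null bands, and switch-probability-after-loss by token asset.

The expected pattern (inherited from the generating models): lag-1
coefficients ordered gain > neutral > loss under saline; under ketamine the
loss coefficient is strongly attenuated; the attenuation is confined to the
drug window; and no condition-by-asset interaction exists.
"""

from pathlib import Path

import pandas as pd

from bmprl import behavior_regression as br, synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = sd.load_study(ROOT / "scratch" / "study")
    out = ROOT / "results"
    for animal in ("P", "Y", "B"):
        coefs = {}
        for condition in ("saline", "ketamine"):
            pooled = sd.pool_condition(study, animal, condition)
            design = br.build_history_design(pooled)
            coefs[condition] = br.fit_choice_logit(design, condition=condition)
            coefs[condition].table.to_csv(
                out / f"coefficients_{animal}_{condition}.csv")
        lag1 = {c: [coefs[c].estimate(o, 1) for o in "GNL"]
                for c in ("saline", "ketamine")}
        print(f"animal {animal}: lag-1 (G, N, L) saline="
              f"{[round(v, 2) for v in lag1['saline']]} ketamine="
              f"{[round(v, 2) for v in lag1['ketamine']]}")

        contrast = br.contrast_conditions(coefs["saline"], coefs["ketamine"])
        contrast.to_csv(out / f"contrast_{animal}.csv")
        sig_loss = contrast.loc[("L", 1)]
        print(f"  loss lag-1 attenuation: diff={sig_loss['diff']:.2f}, "
              f"p={sig_loss['p']:.2g}")

        decay = pd.DataFrame([vars(br.fit_exponential_decay(
            coefs["saline"], coefs["ketamine"], o)) for o in ("G", "N", "L")])
        decay.to_csv(out / f"exp_decay_{animal}.csv", index=False)

        trials = pd.concat([sd.pool_condition(study, animal, c)
                            for c in ("saline", "ketamine")], ignore_index=True)
        tr = br.time_resolved_modulation(trials, n_shuffles=200, seed=1,
                                         min_rows=300)
        tr.to_csv(out / f"time_resolved_{animal}.csv", index=False)
        loss_bins = tr[tr.outcome == "L"]
        outside = loss_bins[(loss_bins["diff"] < loss_bins.band_lo)
                            | (loss_bins["diff"] > loss_bins.band_hi)]
        print(f"  loss modulation outside null band in bins: "
              f"{[f'{r.bin_lo_min:+.0f}..{r.bin_hi_min:+.0f} min' for r in outside.itertuples()]}")

        sw = br.switch_prob_by_asset(trials)
        sw["table"].to_csv(out / f"switch_by_asset_{animal}.csv", index=False)
        print(f"  switch-after-loss condition-by-asset interaction "
              f"p={sw['trend']['interaction_p']:.2f}\n")


if __name__ == "__main__":
    main()
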