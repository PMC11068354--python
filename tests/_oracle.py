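"""Independent brute-force likelihood oracle used only by the tests.

Recomputes the per-trial choice log-likelihood directly from the model
formulas and the raw choice/outcome history, without reusing the package's
state machinery: action values are updated with explicit per-family rules,
and history-dependent terms (perseveration, credit misassignment/spread,
statistical learning) are evaluated from the full history lists each trial
(closed-form geometric sums instead of incremental traces).
"""

import math

CLIP = 1e-12


def _ind(choice):
    return 1.0 if choice == "R" else -1.0


def _delta_of(outcome, dg, dn, dl):
    return {"gain": dg, "neutral": dn, "loss": dl}[outcome]


def oracle_nll(trials, family, p, baseline=None):
    """trials: iterable of (choice, outcome_class, asset_pre); p: dict of params."""
    trials = list(trials)
    choices = [t[0] for t in trials]
    outcomes = [t[1] for t in trials]
    assets = [t[2] for t in trials]
    q = {"L": 0.0, "R": 0.0}
    beta = p.get("beta", 1.0)
    b = baseline or {}
    nll = 0.0
    for t in range(len(trials)):
        x = q["R"] - q["L"]
        if family in ("K6", "K7"):
            prev = _ind(choices[t - 1]) if t >= 1 else 0.0
            x = (1 - p["epsilon"]) * x + p["epsilon"] * prev
        elif family == "K8":
            if t >= 1:
                ds1 = _delta_of(outcomes[t - 1], b["delta_gain"],
                                b["delta_neutral"], b["delta_loss"])
                for j, w in enumerate(("omega1", "omega2", "omega3"), start=2):
                    if t >= j:
                        x += p[w] * _ind(choices[t - j]) * ds1
        elif family == "K9":
            if t >= 1:
                ic1 = _ind(choices[t - 1])
                for j, w in enumerate(("omega1", "omega2", "omega3"), start=2):
                    if t >= j:
                        ds = _delta_of(outcomes[t - j], b["delta_gain"],
                                       b["delta_neutral"], b["delta_loss"])
                        x += p[w] * ic1 * ds
        elif family == "K10":
            freq = {"L": 0.0, "R": 0.0}
            avg_d = 0.0
            for s in range(t):
                decay = p["rho"] ** (t - 1 - s)
                freq[choices[s]] += decay
                avg_d += p["phi"] ** (t - 1 - s) * _delta_of(
                    outcomes[s], b["delta_gain"], b["delta_neutral"], b["delta_loss"])
            rfreq = freq["R"] - freq["L"]
            if abs(rfreq) >= p["tau"]:
                x += p["omega1"] * rfreq * avg_d
        z = max(min(beta * x, 700.0), -700.0)
        a = -z if choices[t] == "R" else z
        term = max(a, 0.0) + math.log1p(math.exp(-abs(a)))
        nll += min(term, -math.log(CLIP))
        q = _oracle_update(q, choices[t], outcomes[t], assets[t], family, p, b)
    return nll


def _oracle_update(q, choice, outcome, asset, family, p, b):
    q = dict(q)
    other = "L" if choice == "R" else "R"
    r_val = {"gain": 1.0, "neutral": 0.0, "loss": -1.0}[outcome]
    if family == "Q":
        q[choice] = (1 - p["alpha_L"]) * q[choice] + p["alpha_L"] * r_val
    elif family in ("QSE", "QSE-R"):
        d = _delta_of(outcome, p["delta_gain"],
                      0.0 if family == "QSE-R" else p["delta_neutral"],
                      p["delta_loss"])
        q[choice] = p["alpha_F"] * q[choice] + d
    elif family in ("DF", "DF-R"):
        d = _delta_of(outcome, p["delta_gain"],
                      0.0 if family == "DF-R" else p["delta_neutral"],
                      p["delta_loss"])
        q[choice] = p["alpha_F_C"] * q[choice] + d
        q[other] = p["alpha_F_UC"] * q[other]
    elif family in ("NDF", "NDF-R"):
        d = _delta_of(outcome, p["delta_gain"],
                      0.0 if family == "NDF-R" else p["delta_neutral"],
                      p["delta_loss"])
        q[choice] = p["alpha_F"] * q[choice] + d
        q[other] = p["alpha_F"] * q[other]
    elif family == "DF-A":
        q[choice] = p["alpha_F_C"] * q[choice] + p["lambda_"] * asset * r_val
        q[other] = p["alpha_F_UC"] * q[other]
    elif family == "NDF-A":
        q[choice] = p["alpha_F"] * q[choice] + p["lambda_"] * asset * r_val
        q[other] = p["alpha_F"] * q[other]
    elif family.startswith("K"):
        dg, dn, dl = b["delta_gain"], b["delta_neutral"], b["delta_loss"]
        a_c, a_uc = b["alpha_F_C"], b["alpha_F_UC"]
        if family == "K1":
            dn, dl = dn + p["k"], dl + p["k"]
        elif family == "K2":
            dn, dl = dn + p["k1"], dl + p["k2"]
        elif family == "K3":
            dg, dn, dl = dg + p["k1"], dn + p["k2"], dl + p["k2"]
        elif family in ("K4", "K7"):
            dg, dn, dl = p["delta_gain"], p["delta_neutral"], p["delta_loss"]
        elif family == "K5":
            a_c, a_uc = p["alpha_F_C"], p["alpha_F_UC"]
        d = _delta_of(outcome, dg, dn, dl)
        if family == "K11":
            d = p["lambda_"] * asset * d
        q[choice] = a_c * q[choice] + d
        q[other] = a_uc * q[other]
    else:
        raise ValueError(family)
    return q
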