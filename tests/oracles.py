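"""Independent brute-force replay of every model's session likelihood.

Deliberately written with plain dicts, the ``math`` module and per-model
branching on canonical names — no shared code with the package — so it can
serve as an oracle for the vectorised/compiled likelihood paths.
"""

import math

REWARD_MODELS = {"M1-1", "M1-2", "M1-3"}
BELIEF_MODELS = {"M2-1", "M2-2", "M2-3"}
BELIEF2_MODELS = {"M3-1", "M3-2", "M3-3"}
THETA_MODELS = {"M1-3", "M2-3", "M3-3", "M4-1", "M4-2"}
EPS = 1e-6


def _clip(p):
    return min(max(p, EPS), 1.0 - EPS)


def oracle_session_loglik(name, params, trials, matrix, reward_scale=1.0):
    """Total log-likelihood of observed choices, replayed step by step.

    ``trials`` is a list of dicts with keys ``opponent`` ("HCO"/"LCO"),
    ``choice`` (1 = swerve), ``opponent_choice`` and ``reward``; ``matrix``
    is the tuple (ss, sg, gs, gg).
    """
    ss, sg, gs, gg = matrix
    A = sg - gg
    B = (ss - sg) - (gs - gg)
    values = {o: {"swerve": 0.0, "go": 0.0} for o in ("HCO", "LCO")}
    belief = {o: 0.5 for o in ("HCO", "LCO")}
    beta = params["beta"]
    theta = params.get("theta", 0.0) if name in THETA_MODELS else 0.0
    total = 0.0
    for tr in trials:
        opp = tr["opponent"]
        if name in REWARD_MODELS or name in ("M0", "M4-1"):
            ev = values[opp]["swerve"] - values[opp]["go"]
        else:
            ev = A + B * belief[opp]
        x = beta * ev + theta
        # log P(choice) under P(swerve) = 1/(1+exp(-x)), evaluated in log
        # space so saturated values stay exact
        if tr["choice"] == 1:
            total += -math.log1p(math.exp(-x)) if x >= 0 else x - math.log1p(math.exp(x))
        else:
            total += -x - math.log1p(math.exp(-x)) if x >= 0 else -math.log1p(math.exp(x))

        if name in ("M0", "M4-1", "M4-2"):
            continue  # no updating
        if name.endswith("-1"):
            alpha = params["alpha"]
        else:
            alpha = params["alpha_h"] if opp == "HCO" else params["alpha_l"]
        if name in REWARD_MODELS:
            key = "swerve" if tr["choice"] == 1 else "go"
            values[opp][key] += alpha * (tr["reward"] / reward_scale - values[opp][key])
        elif name in BELIEF_MODELS:
            belief[opp] += alpha * (tr["opponent_choice"] - belief[opp])
        elif name in BELIEF2_MODELS:
            pc = _clip(belief[opp])
            q = (math.log(pc / (1.0 - pc)) / beta - A) / B
            p_new = (
                belief[opp]
                + alpha * (tr["opponent_choice"] - belief[opp])
                + params["kappa"] * (tr["choice"] - q)
            )
            belief[opp] = _clip(p_new)
        else:
            raise ValueError(name)
    return total
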