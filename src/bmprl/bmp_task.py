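"""Biased matching pennies (BMP) token-game environment.

The environment implements the payoff structure of a competitive two-choice
game in which matching the computer opponent's choice earns tokens, while a
non-matching choice yields either a neutral outcome (zero tokens) or a token
loss.  Loss is more likely on one target ("risky") than the other ("safe");
the risky side is fixed within a block of trials and switches stochastically
afterwards.  Tokens accumulate across trials and are exchanged for juice once
a threshold (six by default) is reached, after which the animal restarts with
a few free tokens.

The computer opponent can either choose uniformly at random or act as a
rational exploiter that scans the recent choice and choice-by-outcome history
for conditional biases and plays to deny the agent's gain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .records import SIDES


@dataclass
class TaskConfig:
    """Payoff, block, and token parameters of the BMP environment.

    ``p_loss_risky`` / ``p_loss_safe`` are the probabilities that a
    non-matching choice on the risky / safe target yields a token loss rather
    than a neutral outcome; loss must be more likely on the risky target.
    """

    gain_tokens: int = 2
    loss_tokens: int = 1
    tokens_to_reward: int = 6
    free_tokens_range: tuple[int, int] = (2, 4)
    block_length: int = 40
    block_switch_prob: float = 0.1
    p_loss_risky: float = 0.75
    p_loss_safe: float = 0.25
    asset_floor: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.block_switch_prob <= 1.0):
            raise ValueError("block_switch_prob must be in (0, 1]")
        if not (0.0 <= self.p_loss_safe < self.p_loss_risky <= 1.0):
            raise ValueError("need 0 <= p_loss_safe < p_loss_risky <= 1")
        if self.gain_tokens not in (1, 2) or self.loss_tokens not in (1, 2):
            raise ValueError("gain_tokens and loss_tokens must be 1 or 2")
        if self.tokens_to_reward <= 0:
            raise ValueError("tokens_to_reward must be positive")
        lo, hi = self.free_tokens_range
        if not (self.asset_floor <= lo <= hi < self.tokens_to_reward):
            raise ValueError("free_tokens_range must lie within the legal asset range")


@dataclass
class BlockState:
    """Which side is currently risky, and how deep into the block we are."""

    risky_side: str = "L"
    trials_in_block: int = 0


@dataclass
class OutcomeEvent:
    outcome_class: str
    token_delta: int
    juice_delivered: bool = False
    asset_pre: int = 0
    asset_post: int = 0


@dataclass
class OpponentConfig:
    """Computer-opponent behavior.

    In ``conditional-probability`` mode the opponent estimates the probability
    of the agent choosing right conditioned on every recent history pattern of
    choices (and of choice-outcome pairs) up to ``history_order`` trials back,
    flags patterns whose conditional choice probability deviates from 0.5 by a
    binomial test at ``significance_level``, and responds to the most
    significant bias by playing the side opposite to the predicted choice —
    denying the agent's gain.  In ``uniform`` mode each side is played with
    probability one half.
    """

    history_order: int = 4
    significance_level: float = 0.05
    exploit_mode: str = "conditional-probability"

    def __post_init__(self) -> None:
        if self.history_order < 0:
            raise ValueError("history_order must be >= 0")
        if self.exploit_mode not in ("conditional-probability", "uniform"):
            raise ValueError(f"unknown exploit_mode: {self.exploit_mode!r}")


class Opponent:
    """Incremental exploiting opponent; keeps conditional counts across trials.

    One counter table per (history kind, order) tracks, for every observed
    pattern of the last ``k`` choices (or choice-outcome pairs), how often the
    agent chose right immediately afterwards.
    """

    def __init__(self, cfg: OpponentConfig):
        self.cfg = cfg
        # counts[(kind, order)][pattern] = [n_right, n_total]
        self.counts: dict[tuple[str, int], dict[tuple, list[int]]] = {
            (kind, k): {}
            for kind in ("choice", "choice_outcome")
            for k in range(1, cfg.history_order + 1)
        }
        self._choices: list[str] = []
        self._outcomes: list[str] = []

    def _patterns(self) -> dict[tuple[str, int], tuple]:
        """Current history patterns keyed by (kind, order)."""
        out = {}
        n = len(self._choices)
        for k in range(1, self.cfg.history_order + 1):
            if n < k:
                break
            out[("choice", k)] = tuple(self._choices[n - k:])
            out[("choice_outcome", k)] = tuple(
                zip(self._choices[n - k:], self._outcomes[n - k:])
            )
        return out

    def choose(self, rng: np.random.Generator) -> str:
        if self.cfg.exploit_mode == "uniform" or not self._choices:
            return SIDES[rng.integers(2)]
        best_p, predicted = 1.0, None
        for key, pattern in self._patterns().items():
            entry = self.counts[key].get(pattern)
            if entry is None or entry[1] < 2:
                continue
            n_right, n_total = entry
            p = stats.binomtest(n_right, n_total, 0.5).pvalue
            if p < self.cfg.significance_level and p < best_p:
                best_p = p
                predicted = "R" if n_right * 2 > n_total else "L"
        if predicted is None:
            return SIDES[rng.integers(2)]
        # play opposite to the predicted agent choice: deny the match/gain
        return "L" if predicted == "R" else "R"

    def observe(self, choice: str, outcome_class: str) -> None:
        """Record the agent's trial after the fact; updates all pattern counts."""
        for key, pattern in self._patterns().items():
            entry = self.counts[key].setdefault(pattern, [0, 0])
            entry[0] += choice == "R"
            entry[1] += 1
        self._choices.append(choice)
        self._outcomes.append(outcome_class)


def opponent_choose(choice_history, outcome_history, cfg: OpponentConfig,
                    rng: np.random.Generator) -> str:
    """Functional form of the opponent: rebuilds counts from the full history.

    Convenient for tests and one-off calls; the simulator uses the incremental
    :class:`Opponent` to avoid quadratic cost.
    """
    if len(choice_history) != len(outcome_history):
        raise ValueError("choice and outcome histories must have equal length")
    opp = Opponent(cfg)
    for c, o in zip(choice_history, outcome_history):
        opp.observe(c, o)
    return opp.choose(rng)


def resolve_outcome(animal: str, opponent: str, block: BlockState,
                    cfg: TaskConfig, rng: np.random.Generator) -> OutcomeEvent:
    """Apply the payoff matrix: match -> gain; non-match -> loss or neutral.

    On a non-match the loss probability depends on whether the agent chose the
    risky or the safe side.
    """
    if animal == opponent:
        return OutcomeEvent("gain", cfg.gain_tokens)
    p_loss = cfg.p_loss_risky if animal == block.risky_side else cfg.p_loss_safe
    if rng.random() < p_loss:
        return OutcomeEvent("loss", -cfg.loss_tokens)
    return OutcomeEvent("neutral", 0)


def apply_tokens(asset_pre: int, event: OutcomeEvent, cfg: TaskConfig,
                 rng: np.random.Generator) -> tuple[int, bool, int | None]:
    """Update the token asset; exchange for juice at the threshold.

    Returns ``(asset_post, juice_delivered, free_tokens_granted)`` where
    ``free_tokens_granted`` is None on non-juice trials.
    """
    if not (cfg.asset_floor <= asset_pre < cfg.tokens_to_reward):
        raise ValueError(f"asset_pre={asset_pre} outside legal range")
    total = max(asset_pre + event.token_delta, cfg.asset_floor)
    if total >= cfg.tokens_to_reward:
        lo, hi = cfg.free_tokens_range
        free = int(rng.integers(lo, hi + 1))
        return free, True, free
    return total, False, None


def maybe_switch_block(block: BlockState, cfg: TaskConfig,
                       rng: np.random.Generator) -> BlockState:
    """Advance the block: after ``block_length`` trials the risky side flips
    with ``block_switch_prob`` per trial; the counter resets on a flip."""
    if block.trials_in_block >= cfg.block_length and rng.random() < cfg.block_switch_prob:
        return BlockState("L" if block.risky_side == "R" else "R", 0)
    return BlockState(block.risky_side, block.trials_in_block)
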