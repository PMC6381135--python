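"""30-round Prisoner's Dilemma sessions against the scripted computer opponent.

The computer plays tit-for-two-tats — it cooperates until the participant
defects twice in a row, then defects until the participant cooperates again —
except in the final two rounds, where it defects unconditionally.  Payoffs are
the percentage profits of the shop-pricing cover story (mutual cooperation
30/30, mutual defection 20/20, unilateral defection 40 against 10), and each
round carries the emotional-feedback label implied by the participant's action
and the between-subjects condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .actions import ACTIONS, C, D, JointHistory
from .automata import get_strategy
from .errors import ConfigurationError, InputError

DECEPTION = 1
NON_DECEPTION = 2

HAPPY = "happy"
NEUTRAL = "neutral"
SAD = "sad"


@dataclass(frozen=True)
class PayoffMatrix:
    """Percent-profit payoffs with the standard PD ordering T > R > P > S."""

    reward: float = 30.0
    temptation: float = 40.0
    punishment: float = 20.0
    sucker: float = 10.0

    def __post_init__(self) -> None:
        if not (self.temptation > self.reward > self.punishment > self.sucker):
            raise ConfigurationError(
                "payoffs must satisfy T > R > P > S; got "
                f"T={self.temptation}, R={self.reward}, P={self.punishment}, S={self.sucker}"
            )


@dataclass(frozen=True)
class Condition:
    """One cell of the 2x2 feedback design.

    ``positive_feedback``: a happy face follows cooperation; ``negative_feedback``:
    a sad face follows defection.  Condition ids 1-4 map to (0,0), (0,1), (1,0),
    (1,1) respectively.
    """

    id: int
    positive_feedback: int
    negative_feedback: int

    _BY_ID = {1: (0, 0), 2: (0, 1), 3: (1, 0), 4: (1, 1)}

    def __post_init__(self) -> None:
        if self.id not in self._BY_ID:
            raise ConfigurationError(f"condition id must be 1-4, got {self.id}")
        if (self.positive_feedback, self.negative_feedback) != self._BY_ID[self.id]:
            raise ConfigurationError(
                f"condition {self.id} must have flags {self._BY_ID[self.id]}, got "
                f"({self.positive_feedback}, {self.negative_feedback})"
            )

    @classmethod
    def from_id(cls, id: int) -> "Condition":
        if id not in cls._BY_ID:
            raise ConfigurationError(f"condition id must be 1-4, got {id}")
        pos, neg = cls._BY_ID[id]
        return cls(id, pos, neg)

    @classmethod
    def from_flags(cls, positive_feedback: int, negative_feedback: int) -> "Condition":
        for id, flags in cls._BY_ID.items():
            if flags == (positive_feedback, negative_feedback):
                return cls(id, *flags)
        raise ConfigurationError("feedback flags must be 0/1")


@dataclass(frozen=True)
class GameConfig:
    rounds_total: int = 30
    endgame_defect_rounds: int = 2
    game_version: int = DECEPTION
    condition: Condition = field(default_factory=lambda: Condition.from_id(1))
    payoffs: PayoffMatrix = field(default_factory=PayoffMatrix)

    def __post_init__(self) -> None:
        if self.endgame_defect_rounds >= self.rounds_total:
            raise ConfigurationError("endgame_defect_rounds must be < rounds_total")
        if self.endgame_defect_rounds < 0 or self.rounds_total < 1:
            raise ConfigurationError("round counts must be non-negative / positive")
        if self.game_version not in (DECEPTION, NON_DECEPTION):
            raise ConfigurationError("game_version must be 1 (deception) or 2 (non-deception)")


@dataclass(frozen=True)
class RoundRecord:
    round: int
    participant_action: str
    computer_action: str
    participant_payoff: float
    computer_payoff: float
    feedback: str


def payoff(
    participant_action: str, computer_action: str, matrix: PayoffMatrix | None = None
) -> tuple[float, float]:
    """(participant, computer) percent profit for one round."""
    m = matrix or PayoffMatrix()
    pair = (participant_action, computer_action)
    if pair == (C, C):
        return (m.reward, m.reward)
    if pair == (D, D):
        return (m.punishment, m.punishment)
    if pair == (D, C):
        return (m.temptation, m.sucker)
    if pair == (C, D):
        return (m.sucker, m.temptation)
    raise InputError(f"invalid action pair {pair}")


def feedback_label(participant_action: str, condition: Condition) -> str:
    """Emotional label of the opponent-face video shown after the round."""
    if participant_action == C:
        return HAPPY if condition.positive_feedback else NEUTRAL
    if participant_action == D:
        return SAD if condition.negative_feedback else NEUTRAL
    raise InputError(f"invalid action {participant_action!r}")


_TF2T = get_strategy("TF2T")


def computer_move(history: JointHistory, round: int, config: GameConfig) -> str:
    """The scripted opponent's action for ``round``.

    ``history`` is written from the participant's perspective (``own`` =
    participant).  Defects unconditionally in the final
    ``endgame_defect_rounds`` rounds; otherwise plays tit-for-two-tats against
    the participant's past actions.
    """
    if not (1 <= round <= config.rounds_total):
        raise InputError(f"round {round} outside 1..{config.rounds_total}")
    if len(history) != round - 1:
        raise InputError(
            f"history has {len(history)} rounds but round {round} needs {round - 1}"
        )
    if round > config.rounds_total - config.endgame_defect_rounds:
        return D
    # From the computer's seat the participant is the opponent.
    mirrored = JointHistory(history.opponent, history.own, history.rounds_total)
    return _TF2T.prescribe(mirrored)


def play_session(
    policy: Callable[[JointHistory], str], config: GameConfig | None = None
) -> list[RoundRecord]:
    """Run a full session of ``rounds_total`` rounds.

    ``policy`` maps the current joint history (participant's view) to the
    participant's next action; the computer follows :func:`computer_move`.
    """
    cfg = config or GameConfig()
    records: list[RoundRecord] = []
    history = JointHistory((), (), cfg.rounds_total)
    for t in range(1, cfg.rounds_total + 1):
        pa = policy(history)
        if pa not in ACTIONS:
            raise InputError(f"policy returned {pa!r}; actions must be 'C' or 'D'")
        ca = computer_move(history, t, cfg)
        pp, cp = payoff(pa, ca, cfg.payoffs)
        records.append(
            RoundRecord(t, pa, ca, pp, cp, feedback_label(pa, cfg.condition))
        )
        history = history.appended(pa, ca)
    return records


def session_history(records: Sequence[RoundRecord], rounds_total: int | None = None) -> JointHistory:
    """Reassemble a JointHistory from round records."""
    return JointHistory(
        tuple(r.participant_action for r in records),
        tuple(r.computer_action for r in records),
        rounds_total or len(records),
    )
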