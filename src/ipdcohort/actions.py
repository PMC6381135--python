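"""Action alphabet and joint play histories for the iterated Prisoner's Dilemma.

Actions are serialized as the single characters ``"C"`` (cooperate — keep the
standard price in the shop cover story) and ``"D"`` (defect — undercut with the
sale price).  A :class:`JointHistory` pairs the two players' realized action
sequences round by round; it is the information set every strategy automaton
and every likelihood computation conditions on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import InputError

C = "C"
D = "D"
ACTIONS = (C, D)


def flip(action: str) -> str:
    """Return the opposite action (the tremble outcome)."""
    return D if action == C else C


def validate_actions(seq: Iterable[str], label: str = "actions") -> tuple[str, ...]:
    """Coerce to a tuple of action symbols, rejecting anything outside {C, D}."""
    out = tuple(seq)
    for a in out:
        if a not in ACTIONS:
            raise InputError(f"invalid symbol {a!r} in {label}: actions must be 'C' or 'D'")
    return out


@dataclass(frozen=True)
class JointHistory:
    """Realized paired actions of the participant and the computer opponent.

    Rounds are indexed 1-based; both sequences cover rounds ``1..len``.  A
    history of length ``t - 1`` is exactly what is observable when choosing an
    action for round ``t`` (moves within a round are simultaneous).
    """

    own: tuple[str, ...] = field(default_factory=tuple)
    opponent: tuple[str, ...] = field(default_factory=tuple)
    rounds_total: int = 30

    def __post_init__(self) -> None:
        object.__setattr__(self, "own", validate_actions(self.own, "own actions"))
        object.__setattr__(self, "opponent", validate_actions(self.opponent, "opponent actions"))
        if len(self.own) != len(self.opponent):
            raise InputError(
                f"own/opponent sequences differ in length ({len(self.own)} vs {len(self.opponent)})"
            )
        if self.rounds_total < 1:
            raise InputError("rounds_total must be positive")
        if len(self.own) > self.rounds_total:
            raise InputError("history longer than rounds_total")

    def __len__(self) -> int:
        return len(self.own)

    def truncated(self, t: int) -> "JointHistory":
        """History of the first ``t`` rounds."""
        return JointHistory(self.own[:t], self.opponent[:t], self.rounds_total)

    def appended(self, own: str, opponent: str) -> "JointHistory":
        return JointHistory(self.own + (own,), self.opponent + (opponent,), self.rounds_total)

    @classmethod
    def from_sequences(
        cls, own: Sequence[str], opponent: Sequence[str], rounds_total: int = 30
    ) -> "JointHistory":
        return cls(tuple(own), tuple(opponent), rounds_total)
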