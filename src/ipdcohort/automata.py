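"""Deterministic IPD strategies as finite automata over joint histories.

Each catalogued strategy is a pure function from the realized joint history to
the action it prescribes for the next round.  Internally every strategy is a
small state machine driven one round at a time, so evaluating a prescription
after ``t`` rounds costs O(t) and simulating a whole game costs O(T).

The catalogue covers the classic reactive family used in strategy-frequency
estimation for repeated games: the always-cooperate / always-defect constants,
tit-for-tat and its lenient variants (TF2T, TF3T forgive only after two or
three consecutive opponent defections), harsher punishers (2TFT punishes a
single defection with two rounds of defection, 2TF2T demands two consecutive
cooperations to end its punishment), the grim triggers (Grim, Grim2, Grim3),
and the suspicious opener DTFT.  All of them condition on the *opponent's*
actions only; a player's own trembles influence future prescriptions solely
through the opponent's reaction to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

from .actions import C, D, JointHistory
from .errors import ConfigurationError

__all__ = [
    "StrategyAutomaton",
    "Constant",
    "WindowPunisher",
    "ConsecutiveTrigger",
    "CATALOGUE",
    "PRESETS",
    "build_strategy_set",
    "get_strategy",
    "prescribe",
    "prescribed_sequence",
    "registry",
    "registry_json",
]


@dataclass(frozen=True)
class StrategyAutomaton:
    """Base class: a named deterministic map history -> next action.

    ``memory_depth`` is the number of past rounds the prescription actually
    depends on (``None`` for unbounded, e.g. trigger strategies).
    """

    abbreviation: str
    name: str
    description: str
    memory_depth: int | None

    # -- state machine interface -------------------------------------------------
    def initial_state(self):
        raise NotImplementedError

    def action(self, state) -> str:
        raise NotImplementedError

    def transition(self, state, own: str, opp: str):
        raise NotImplementedError

    # -- history interface -------------------------------------------------------
    def prescribe(self, history: JointHistory) -> str:
        """Action prescribed for the round following ``history``."""
        state = self.initial_state()
        for own, opp in zip(history.own, history.opponent):
            state = self.transition(state, own, opp)
        return self.action(state)

    def prescribed_sequence(self, history: JointHistory) -> tuple[str, ...]:
        """Prescriptions for rounds ``1..T`` conditioned on the realized play.

        Element ``t`` equals ``prescribe`` on the history truncated to rounds
        ``1..t-1``; this is the sequence a tremble likelihood compares the
        realized choices against.
        """
        out = []
        state = self.initial_state()
        for own, opp in zip(history.own, history.opponent):
            out.append(self.action(state))
            state = self.transition(state, own, opp)
        return tuple(out)

    def parameters(self) -> dict:
        return {}


@dataclass(frozen=True)
class Constant(StrategyAutomaton):
    """ALLC / ALLD: play one action unconditionally."""

    constant_action: str = C

    def initial_state(self):
        return None

    def action(self, state) -> str:
        return self.constant_action

    def transition(self, state, own, opp):
        return None

    def parameters(self) -> dict:
        return {"action": self.constant_action}


@dataclass(frozen=True)
class WindowPunisher(StrategyAutomaton):
    """Defect iff the opponent defected within the last ``window`` rounds.

    ``window=1`` is plain tit-for-tat; ``window=2`` is "two tits for a tat"
    (every defection is answered with two rounds of defection).  ``first_action``
    lets DTFT open with a defection before reverting to tit-for-tat.
    """

    window: int = 1
    first_action: str = C

    def initial_state(self):
        # tuple of the last `window` opponent actions, most recent last
        return ()

    def action(self, state) -> str:
        if not state:
            return self.first_action
        return D if D in state else C

    def transition(self, state, own, opp):
        return (state + (opp,))[-self.window :]

    def parameters(self) -> dict:
        return {"window": self.window, "first_action": self.first_action}


@dataclass(frozen=True)
class ConsecutiveTrigger(StrategyAutomaton):
    """Cooperate until the opponent defects ``n_trigger`` times in a row.

    What ends the punishment phase is governed by ``forgiveness``:

    - ``"one_c"``: a single opponent cooperation restores cooperation
      (TF2T, TF3T);
    - ``"two_c"``: the opponent must cooperate twice in a row (2TF2T) —
      a three-phase automaton: content / punishing / re-earning;
    - ``"never"``: defect forever (Grim, Grim2, Grim3).
    """

    n_trigger: int = 1
    forgiveness: str = "never"

    def initial_state(self):
        # (punishing, consecutive opponent D while content, consecutive C while punishing)
        return (False, 0, 0)

    def action(self, state) -> str:
        return D if state[0] else C

    def transition(self, state, own, opp):
        punishing, consec_d, consec_c = state
        if punishing:
            if self.forgiveness == "never":
                return state
            if opp == C:
                consec_c += 1
                need = 1 if self.forgiveness == "one_c" else 2
                if consec_c >= need:
                    return (False, 0, 0)
                return (True, 0, consec_c)
            return (True, 0, 0)
        if opp == D:
            consec_d += 1
            if consec_d >= self.n_trigger:
                return (True, 0, 0)
            return (False, consec_d, 0)
        return (False, 0, 0)

    def parameters(self) -> dict:
        return {"n_trigger": self.n_trigger, "forgiveness": self.forgiveness}


def _make_catalogue() -> dict[str, StrategyAutomaton]:
    entries = [
        Constant("ALLC", "Always cooperate", "Cooperate at each round", 0, C),
        Constant("ALLD", "Always defect", "Defect at each round", 0, D),
        WindowPunisher(
            "TFT", "Tit for tat", "Cooperate first, then copy the opponent's last action", 1, 1, C
        ),
        ConsecutiveTrigger(
            "TF2T",
            "Tit for two tats",
            "Cooperate until the opponent defects twice in a row, "
            "then defect till the opponent cooperates again",
            2,
            2,
            "one_c",
        ),
        ConsecutiveTrigger(
            "TF3T",
            "Tit for three tats",
            "Cooperate until the opponent defects three times in a row, "
            "then defect till the opponent cooperates again",
            3,
            3,
            "one_c",
        ),
        WindowPunisher(
            "2TFT",
            "Two tits for tat",
            "Defect if the opponent defected in either of the last two rounds",
            2,
            2,
            C,
        ),
        ConsecutiveTrigger(
            "2TF2T",
            "Two tits for two tats",
            "Cooperate until the opponent defects twice in a row, "
            "then defect till the opponent cooperates twice in a row",
            None,
            2,
            "two_c",
        ),
        ConsecutiveTrigger(
            "Grim",
            "Grim trigger",
            "Cooperate until the opponent defects, then defect forever",
            None,
            1,
            "never",
        ),
        ConsecutiveTrigger(
            "Grim2",
            "Lenient grim 2",
            "Cooperate until the opponent defects twice in a row, then defect forever",
            None,
            2,
            "never",
        ),
        ConsecutiveTrigger(
            "Grim3",
            "Lenient grim 3",
            "Cooperate until the opponent defects three times in a row, then defect forever",
            None,
            3,
            "never",
        ),
        WindowPunisher(
            "DTFT",
            "Suspicious tit for tat",
            "Defect in the first round, then play tit for tat",
            1,
            1,
            D,
        ),
    ]
    return {s.abbreviation: s for s in entries}


CATALOGUE: dict[str, StrategyAutomaton] = _make_catalogue()

#: Named subsets of the catalogue.  ``table6`` is the four-strategy set used
#: for the headline strategy-frequency table (one representative each of the
#: cooperative, forgiving, unforgiving and defective families).
PRESETS: dict[str, tuple[str, ...]] = {
    "table6": ("TF3T", "2TF2T", "Grim", "ALLD"),
    "recovery": ("ALLD", "2TF2T", "TF3T", "Grim", "ALLC"),
    "full": tuple(CATALOGUE),
}


def get_strategy(abbreviation: str) -> StrategyAutomaton:
    try:
        return CATALOGUE[abbreviation]
    except KeyError:
        raise ConfigurationError(
            f"unknown strategy {abbreviation!r}; valid names: {', '.join(CATALOGUE)}"
        ) from None


def build_strategy_set(names: Sequence[str]) -> list[StrategyAutomaton]:
    """Resolve abbreviations (or a preset name) to automata, in order.

    Raises :class:`ConfigurationError` on unknown or duplicated names.
    """
    if isinstance(names, str):
        if names in PRESETS:
            names = PRESETS[names]
        else:
            raise ConfigurationError(
                f"unknown preset {names!r}; valid presets: {', '.join(PRESETS)}"
            )
    seen = set()
    out = []
    for n in names:
        if n in seen:
            raise ConfigurationError(f"duplicate strategy name {n!r} in request")
        seen.add(n)
        out.append(get_strategy(n))
    return out


def prescribe(strategy: StrategyAutomaton | str, history: JointHistory) -> str:
    """Action ``strategy`` dictates for the next round given ``history``."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    return strategy.prescribe(history)


def prescribed_sequence(strategy: StrategyAutomaton | str, history: JointHistory) -> tuple[str, ...]:
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    return strategy.prescribed_sequence(history)


def registry() -> dict:
    """Machine-readable catalogue: abbreviation -> description and parameters."""
    return {
        ab: {
            "name": s.name,
            "description": s.description,
            "memory_depth": s.memory_depth,
            "parameters": s.parameters(),
            "kind": type(s).__name__,
        }
        for ab, s in CATALOGUE.items()
    }


def registry_json(indent: int = 2) -> str:
    return json.dumps({"strategies": registry(), "presets": {k: list(v) for k, v in PRESETS.items()}}, indent=indent)
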