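"""Two-player 3x3 normal-form games and strategy-based choice labelling.

A game pits the human row player (actions Top / Middle / Bottom) against a
rational column player (Left / Middle / Right).  Every game used here has a
unique strict pure-strategy Nash equilibrium, and the three decision rules
studied — Equilibrium, Naive (highest own average payoff) and Coordination
(largest joint payoff, smallest payoff difference) — predict three distinct
row actions, so the observed choice maps bijectively to a strategy label.

Two structural categories are generated: DO games, where the column player
has a strictly dominant action (the game is solvable by iterated dominance),
and UE games, where neither player has a dominant action but the strict
equilibrium is still unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ROW_ACTIONS = ("Top", "Middle", "Bottom")
COL_ACTIONS = ("Left", "Middle", "Right")


class GameCategory(str, Enum):
    """DO: column player has a strictly dominant action; UE: nobody does."""

    DO = "DO"
    UE = "UE"


class StrategyLabel(str, Enum):
    EQUILIBRIUM = "Equilibrium"
    NAIVE = "Naive"
    COORDINATION = "Coordination"


STRATEGIES = (StrategyLabel.EQUILIBRIUM, StrategyLabel.NAIVE, StrategyLabel.COORDINATION)


class InvalidGameError(ValueError):
    """Raised when a game violates the study's structural assumptions."""


@dataclass(frozen=True)
class Game:
    """A 3x3 normal-form game with integer payoffs.

    ``row_payoffs[r, c]`` is the row player's payoff when the row player
    plays action ``r`` and the column player plays action ``c``;
    ``col_payoffs[r, c]`` is the column player's payoff in the same cell.
    """

    game_id: str
    row_payoffs: np.ndarray
    col_payoffs: np.ndarray
    category: GameCategory = GameCategory.UE

    def __post_init__(self) -> None:
        for name in ("row_payoffs", "col_payoffs"):
            m = np.asarray(getattr(self, name), dtype=int)
            if m.shape != (3, 3):
                raise InvalidGameError(f"{name} must be a 3x3 matrix, got {m.shape}")
            object.__setattr__(self, name, m)
        object.__setattr__(self, "category", GameCategory(self.category))

    def to_dict(self) -> dict:
        return {
            "game_id": self.game_id,
            "category": self.category.value,
            "row_payoffs": self.row_payoffs.tolist(),
            "col_payoffs": self.col_payoffs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Game":
        return cls(
            game_id=d["game_id"],
            row_payoffs=np.asarray(d["row_payoffs"], dtype=int),
            col_payoffs=np.asarray(d["col_payoffs"], dtype=int),
            category=GameCategory(d["category"]),
        )


def pure_nash_equilibria(game: Game) -> set[tuple[str, str]]:
    """All cells where each action is a *strict* best response to the other.

    Returns the (row_action, col_action) pairs; for valid study games the
    set has exactly one element.  An empty set is a legal result for
    arbitrary matrices (e.g. all-ties games have no strict equilibrium).
    """
    out: set[tuple[str, str]] = set()
    R, C = game.row_payoffs, game.col_payoffs
    for r in range(3):
        for c in range(3):
            row_strict = all(R[r, c] > R[q, c] for q in range(3) if q != r)
            col_strict = all(C[r, c] > C[r, q] for q in range(3) if q != c)
            if row_strict and col_strict:
                out.add((ROW_ACTIONS[r], COL_ACTIONS[c]))
    return out


def dominant_action(game: Game, player: str) -> str | None:
    """The player's strictly dominant action, or None if there is none.

    An action strictly dominates when it yields a strictly higher payoff
    than every alternative against every opposing action.
    """
    if player == "row":
        payoff = game.row_payoffs  # compare rows, for every column
        actions, axis = ROW_ACTIONS, 0
    elif player == "col":
        payoff = game.col_payoffs.T  # compare columns, for every row
        actions, axis = COL_ACTIONS, 0
    else:
        raise ValueError(f"player must be 'row' or 'col', got {player!r}")
    for a in range(3):
        if all(np.all(payoff[a] > payoff[b]) for b in range(3) if b != a):
            return actions[a]
    return None


def predict_equilibrium_action(game: Game) -> str:
    """Row action of the unique strict Nash equilibrium."""
    ne = pure_nash_equilibria(game)
    if len(ne) != 1:
        raise InvalidGameError(
            f"game {game.game_id}: expected exactly 1 strict Nash equilibrium, found {len(ne)}"
        )
    return next(iter(ne))[0]


def predict_naive_action(game: Game) -> str:
    """Row action with the highest average own payoff (ties rejected)."""
    means = game.row_payoffs.mean(axis=1)
    best = np.flatnonzero(means == means.max())
    if len(best) != 1:
        raise InvalidGameError(f"game {game.game_id}: tie in row-average payoffs")
    return ROW_ACTIONS[best[0]]


def predict_coordination_action(game: Game) -> str:
    """Row action of the cell with the largest payoff sum, tie-broken by the
    smallest absolute payoff difference between the two players.

    The criterion is lexicographic: maximise ``row+col`` first, then
    minimise ``|row-col|``; a game is rejected if a tie survives both keys.
    """
    sums = game.row_payoffs + game.col_payoffs
    diffs = np.abs(game.row_payoffs - game.col_payoffs)
    top = sums == sums.max()
    cand = np.flatnonzero(top & (diffs == diffs[top].min()))
    if len(cand) != 1:
        raise InvalidGameError(
            f"game {game.game_id}: coordination criterion tied after tie-break"
        )
    return ROW_ACTIONS[cand[0] // 3]


def strategy_predictions(game: Game) -> dict[StrategyLabel, str]:
    return {
        StrategyLabel.EQUILIBRIUM: predict_equilibrium_action(game),
        StrategyLabel.NAIVE: predict_naive_action(game),
        StrategyLabel.COORDINATION: predict_coordination_action(game),
    }


def label_choice(game: Game, chosen: str) -> StrategyLabel:
    """Map a chosen row action to the unique strategy that predicts it."""
    if chosen not in ROW_ACTIONS:
        raise ValueError(f"unknown row action {chosen!r}")
    preds = strategy_predictions(game)
    if len(set(preds.values())) != 3:
        raise InvalidGameError(
            f"game {game.game_id}: strategy predictions are not pairwise distinct"
        )
    for strat, action in preds.items():
        if action == chosen:
            return strat
    raise AssertionError("unreachable: three distinct predictions cover all actions")


def is_equilibrium_choice(game: Game, chosen: str) -> bool:
    """Binary view used by classification task 1 (equilibrium or not)."""
    return label_choice(game, chosen) is StrategyLabel.EQUILIBRIUM


def _satisfies_invariants(game: Game) -> bool:
    if len(pure_nash_equilibria(game)) != 1:
        return False
    col_dom = dominant_action(game, "col")
    if game.category is GameCategory.DO and col_dom is None:
        return False
    if game.category is GameCategory.UE and (
        col_dom is not None or dominant_action(game, "row") is not None
    ):
        return False
    try:
        preds = strategy_predictions(game)
    except InvalidGameError:
        return False
    return len(set(preds.values())) == 3


def generate_game(
    category: GameCategory | str,
    rng: np.random.Generator,
    payoff_range: tuple[int, int] = (1, 9),
    max_attempts: int = 1_000_000,
    game_id: str | None = None,
) -> Game:
    """Rejection-sample an integer game satisfying all category invariants.

    Draws payoff matrices uniformly from ``payoff_range`` (inclusive) until
    the candidate has a unique strict equilibrium, the requested dominance
    structure, and three pairwise-distinct strategy predictions.
    """
    category = GameCategory(category)
    lo, hi = payoff_range
    if hi - lo < 2:
        raise ValueError("payoff_range too narrow to admit generic games")
    for attempt in range(max_attempts):
        rp = rng.integers(lo, hi + 1, size=(3, 3))
        cp = rng.integers(lo, hi + 1, size=(3, 3))
        g = Game(
            game_id=game_id or f"{category.value}-{attempt}",
            row_payoffs=rp,
            col_payoffs=cp,
            category=category,
        )
        if _satisfies_invariants(g):
            return g
    raise RuntimeError(
        f"no valid {category.value} game found in {max_attempts} attempts; "
        "constraints may be infeasible for this payoff range"
    )


def generate_battery(
    rng: np.random.Generator,
    n_do: int = 5,
    n_ue: int = 5,
    payoff_range: tuple[int, int] = (1, 9),
) -> list[Game]:
    """A battery of distinct games, ``n_do`` DO + ``n_ue`` UE.

    The equilibrium row is re-randomised across draws; batteries whose
    equilibrium rows are all identical are rejected (the original study
    randomised strategy locations to prevent positional shortcuts).
    """
    while True:
        games: list[Game] = []
        seen: set[bytes] = set()
        for cat, n in ((GameCategory.DO, n_do), (GameCategory.UE, n_ue)):
            for i in range(n):
                while True:
                    g = generate_game(cat, rng, payoff_range, game_id=f"{cat.value}{i+1}")
                    key = g.row_payoffs.tobytes() + g.col_payoffs.tobytes()
                    if key not in seen:
                        seen.add(key)
                        games.append(g)
                        break
        eq_rows = {predict_equilibrium_action(g) for g in games}
        if len(games) <= 1 or len(eq_rows) > 1:
            return games


def write_games(games: Iterable[Game], path: str | Path) -> None:
    Path(path).write_text(json.dumps([g.to_dict() for g in games], indent=2))


def read_games(path: str | Path) -> list[Game]:
    return [Game.from_dict(d) for d in json.loads(Path(path).read_text())]
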