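"""Mechanics of the multi-round investor-trustee trust game.

Each of the 10 rounds starts with a fresh endowment of 20 coins for the
investor.  The investor sends ``a_I`` coins, the transfer is tripled in
transit, and the trustee returns ``a_T`` coins of the tripled amount.
Round payoffs are

    chi_I = (20 - a_I) + a_T        (investor)
    chi_T = 3 * a_I   - a_T         (trustee)

so each legal action pair conserves ``chi_I + chi_T = 20 + 2*a_I``.

For tractability the investor's action space is discretized into five
bins with representatives {0, 5, 10, 15, 20}, and the trustee's repayment
is one of five fractions {0, 1/6, 1/3, 1/2, 2/3} of the tripled
investment.  Every legal repayment is a multiple of 2.5 coins, hence
exactly representable as a binary float; fractions are nevertheless
exposed as exact rationals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable

ENDOWMENT = 20
MULTIPLIER = 3
N_ROUNDS = 10

#: representative investments, one per bin
INVESTOR_ACTIONS: tuple[int, ...] = (0, 5, 10, 15, 20)

#: inclusive raw-coin bins, aligned with INVESTOR_ACTIONS
INVESTOR_BINS: tuple[tuple[int, int], ...] = (
    (0, 2), (3, 7), (8, 12), (13, 17), (18, 20))

#: repayment fractions of the tripled investment
TRUSTEE_FRACTIONS: tuple[Fraction, ...] = (
    Fraction(0), Fraction(1, 6), Fraction(1, 3), Fraction(1, 2), Fraction(2, 3))


def discretize_investment(raw: int) -> int:
    """Map a raw 0-20 coin investment to its bin representative."""
    if isinstance(raw, bool) or not float(raw).is_integer():
        raise ValueError(f"investment must be an integer number of coins, got {raw!r}")
    raw = int(raw)
    if not 0 <= raw <= ENDOWMENT:
        raise ValueError(f"investment {raw} outside the 0..{ENDOWMENT} coin range")
    for (lo, hi), rep in zip(INVESTOR_BINS, INVESTOR_ACTIONS):
        if lo <= raw <= hi:
            return rep
    raise AssertionError("bins must partition 0..20")  # pragma: no cover


def trustee_actions(a_I: int) -> tuple[Fraction, ...]:
    """Legal repayments for an investment, as exact rationals.

    A zero investment forces the single repayment 0.
    """
    _check_investment(a_I)
    if a_I == 0:
        return (Fraction(0),)
    return tuple(f * MULTIPLIER * a_I for f in TRUSTEE_FRACTIONS)


def trustee_actions_coins(a_I: int) -> tuple[float, ...]:
    """Legal repayments as floats (all exact multiples of 2.5 coins)."""
    return tuple(float(a) for a in trustee_actions(a_I))


def compute_payoffs(a_I: int, a_T: float) -> tuple[float, float]:
    """Round payoffs (chi_I, chi_T) for a legal action pair."""
    _check_pair(a_I, a_T)
    return (ENDOWMENT - a_I) + a_T, MULTIPLIER * a_I - a_T


def _check_investment(a_I: int) -> None:
    if a_I not in INVESTOR_ACTIONS:
        raise ValueError(
            f"investment {a_I!r} is not a bin representative {INVESTOR_ACTIONS}")


def _check_pair(a_I: int, a_T: float) -> None:
    _check_investment(a_I)
    legal = trustee_actions_coins(a_I)
    if float(a_T) not in legal:
        raise ValueError(
            f"repayment {a_T!r} is illegal for investment {a_I}; legal set {legal}")


@dataclass(frozen=True)
class Round:
    """One completed round: (index, investment, repayment)."""

    index: int
    a_I: int
    a_T: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"round index must be >= 1, got {self.index}")
        _check_pair(self.a_I, self.a_T)

    @property
    def fraction(self) -> Fraction | None:
        """Repayment fraction of the tripled investment; None if a_I == 0."""
        if self.a_I == 0:
            return None
        return Fraction(self.a_T).limit_denominator(6) / (MULTIPLIER * self.a_I)

    @property
    def payoffs(self) -> tuple[float, float]:
        return compute_payoffs(self.a_I, self.a_T)


@dataclass
class GameTrajectory:
    """Ordered rounds of one subject-session."""

    subject_id: str
    timepoint: str
    rounds: list[Round] = field(default_factory=list)
    n_rounds: int = N_ROUNDS  # overridable only for truncated test games

    def __post_init__(self) -> None:
        if len(self.rounds) != self.n_rounds:
            raise ValueError(
                f"{self.subject_id}/{self.timepoint}: expected {self.n_rounds} rounds, "
                f"got {len(self.rounds)}")
        indices = [r.index for r in self.rounds]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("round indices must be strictly increasing")

    @property
    def investments(self) -> list[int]:
        return [r.a_I for r in self.rounds]

    @property
    def repayments(self) -> list[float]:
        return [r.a_T for r in self.rounds]

    @property
    def fractions(self) -> list[Fraction | None]:
        return [r.fraction for r in self.rounds]

    def action_pairs(self) -> list[tuple[int, float]]:
        return [(r.a_I, r.a_T) for r in self.rounds]

    @classmethod
    def from_actions(cls, subject_id: str, timepoint: str,
                     pairs: Iterable[tuple[int, float]],
                     n_rounds: int | None = None) -> "GameTrajectory":
        rounds = [Round(i + 1, a_I, float(a_T)) for i, (a_I, a_T) in enumerate(pairs)]
        return cls(subject_id, timepoint, rounds,
                   n_rounds=len(rounds) if n_rounds is None else n_rounds)


def total_payoff_investor(traj: GameTrajectory) -> float:
    """Sum of chi_I over rounds (endowments are not carried over)."""
    return sum(r.payoffs[0] for r in traj.rounds)
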