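"""Decision contexts and payoff rules for the five economic games.

Each game presents a participant with a finite, ordered menu of options;
every option maps to an :class:`Allocation` — the (self, other) monetary
outcome in JPY implied by choosing it.  The games:

* **DG** (dictator game): split an endowment E with a passive recipient in
  JPY 100 steps; played at seven endowments.
* **PDG** (prisoner's dilemma game): both players send 0–1000 in JPY 100
  steps; the partner receives double the amount sent.
* **PGG** (public goods game): contribute 0–1000 to a pool that is doubled
  and shared equally among the group (nominally 10 players).
* **TG** (trust game): the truster sends 0–1000, tripled in transit; the
  trustee chooses what fraction of the tripled amount to return (elicited by
  the strategy method for every transfer 100–1000).
* **UG** (ultimatum game): the proposer offers part of JPY 1500; the
  responder accepts or rejects each of the 16 possible offers (strategy
  method); rejection leaves both with nothing.

In the simultaneous-move games (PDG, PGG) and for the truster, the chooser's
payoff depends on the co-player's unobserved action, so contexts are built
against an assumed co-player behaviour collected in :class:`BeliefConfig`.
The same beliefs must be used when simulating choices and when fitting, so
that the forward and inverse models agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple, Union

import pandas as pd

from .errors import ConfigurationError, DataError, InvalidInputError

__all__ = [
    "Allocation",
    "DecisionContext",
    "BeliefConfig",
    "GAMES",
    "DEFAULT_DG_ENDOWMENTS",
    "STEP",
    "build_dg_contexts",
    "pdg_realized_payoffs",
    "build_pdg_context",
    "build_pgg_context",
    "build_tg_truster_context",
    "build_tg_trustee_contexts",
    "build_ug_proposer_context",
    "build_ug_responder_contexts",
    "build_schedule",
    "contexts_to_frame",
    "contexts_from_frame",
]

GAMES = (
    "DG",
    "PDG",
    "PGG",
    "TG_TRUSTER",
    "TG_TRUSTEE",
    "UG_PROPOSER",
    "UG_RESPONDER",
)

#: Endowments of the seven dictator-game rounds, in the order played.
DEFAULT_DG_ENDOWMENTS = (1000, 300, 400, 600, 700, 1200, 1300)

#: Monetary grid step (JPY) for every transfer/offer decision.
STEP = 100

Label = Union[int, str]


@dataclass(frozen=True)
class Allocation:
    """A (self, other) payoff pair in JPY."""

    x: float  # self payoff
    y: float  # other payoff

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"allocation must be finite, got {self}")
        if self.x < 0 or self.y < 0:
            raise InvalidInputError(f"allocation must be non-negative, got {self}")


@dataclass(frozen=True)
class DecisionContext:
    """One decision situation: an ordered menu of labelled allocations.

    ``accept_probs``, when present, holds one probability per option and marks
    the context as an expected-value menu: the utility of option *i* is
    ``accept_probs[i] * U(options[i])`` (the complementary outcome being the
    zero allocation, whose utility is identically 0).  Only the ultimatum-game
    proposer in ``rejection_belief`` mode uses this.
    """

    game: str
    context_param: float
    options: Tuple[Tuple[Label, Allocation], ...]
    accept_probs: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        if self.game not in GAMES:
            raise InvalidInputError(f"unknown game {self.game!r}")
        if len(self.options) < 2:
            raise InvalidInputError("a context needs at least two options")
        labels = [lab for lab, _ in self.options]
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"duplicate option labels in {self.game} context")
        if self.accept_probs is not None and len(self.accept_probs) != len(self.options):
            raise InvalidInputError("accept_probs length must match options")

    @property
    def labels(self) -> Tuple[Label, ...]:
        return tuple(lab for lab, _ in self.options)

    @property
    def key(self) -> Tuple[str, float]:
        """Identifier used to join behaviour rows back to their context."""
        return (self.game, round(float(self.context_param), 6))

    def allocation(self, label: Label) -> Allocation:
        for lab, alloc in self.options:
            if lab == label:
                return alloc
        raise KeyError(f"label {label!r} not in {self.game} context {self.context_param}")


@dataclass(frozen=True)
class BeliefConfig:
    """Assumed co-player behaviour for the simultaneous-move decisions.

    Defaults are neutral: midpoint contributions for PDG/PGG and the
    break-even return fraction 1/3 for the truster (at which transferring is
    payoff-neutral).  The proposer is modelled as a pure distribution choice
    by default; ``rejection_belief`` mode instead weights each offer by the
    acceptance probability of a softmax responder with
    ``ug_proposer_rejection_params``.
    """

    pdg_opponent_contribution: float = 500.0
    pgg_other_contribution: float = 500.0
    tg_expected_return_fraction: float = 1.0 / 3.0
    ug_proposer_mode: str = "pure_distribution"
    ug_proposer_rejection_params: Optional[object] = None  # PreferenceParams

    def __post_init__(self):
        if not 0 <= self.pdg_opponent_contribution <= 1000:
            raise ConfigurationError("pdg_opponent_contribution must lie in [0, 1000]")
        if not 0 <= self.pgg_other_contribution <= 1000:
            raise ConfigurationError("pgg_other_contribution must lie in [0, 1000]")
        if not 0 <= self.tg_expected_return_fraction <= 1:
            raise ConfigurationError("tg_expected_return_fraction must lie in [0, 1]")
        if self.ug_proposer_mode not in ("pure_distribution", "rejection_belief"):
            raise ConfigurationError(
                f"unknown ug_proposer_mode {self.ug_proposer_mode!r}"
            )
        if (
            self.ug_proposer_mode == "rejection_belief"
            and self.ug_proposer_rejection_params is None
        ):
            raise ConfigurationError(
                "rejection_belief mode requires ug_proposer_rejection_params"
            )


def _money_grid(limit: float, step: int = STEP) -> range:
    lim = int(round(limit))
    if lim <= 0 or lim != limit or lim % step != 0:
        raise InvalidInputError(f"amount {limit!r} is not a positive multiple of {step}")
    return range(0, lim + step, step)


def build_dg_contexts(
    endowments: Sequence[int] = DEFAULT_DG_ENDOWMENTS,
) -> list[DecisionContext]:
    """Dictator-game contexts, one per endowment.

    Option label ``a`` is the amount given to the recipient; the dictator
    keeps ``E - a``.
    """
    contexts = []
    for e in endowments:
        opts = tuple((a, Allocation(e - a, a)) for a in _money_grid(e))
        contexts.append(DecisionContext("DG", float(e), opts))
    return contexts


def pdg_realized_payoffs(
    c_self: float, c_other: float, endowment: float = 1000, multiplier: float = 2
) -> Allocation:
    """Realised PDG payoffs when the players send ``c_self`` and ``c_other``.

    Each player keeps the unsent endowment and receives ``multiplier`` times
    what the other sent.
    """
    grid = set(_money_grid(endowment))
    if c_self not in grid or c_other not in grid:
        raise InvalidInputError(
            f"contributions ({c_self}, {c_other}) must lie on the 0..{endowment} "
            f"grid in steps of {STEP}"
        )
    x = endowment - c_self + multiplier * c_other
    y = endowment - c_other + multiplier * c_self
    return Allocation(x, y)


def build_pdg_context(beliefs: BeliefConfig = BeliefConfig()) -> DecisionContext:
    """PDG contribution menu against the believed opponent contribution."""
    b = beliefs.pdg_opponent_contribution
    opts = tuple((c, pdg_realized_payoffs(c, b)) for c in _money_grid(1000))
    return DecisionContext("PDG", b, opts)


def build_pgg_context(
    beliefs: BeliefConfig = BeliefConfig(),
    group_size: int = 10,
    multiplier: float = 2,
    endowment: float = 1000,
) -> DecisionContext:
    """PGG contribution menu; the other payoff is a representative other's.

    All ``group_size - 1`` co-players are assumed to contribute
    ``beliefs.pgg_other_contribution`` each; the pool is multiplied and split
    equally, so the chooser's share of their own contribution is
    ``multiplier / group_size`` per JPY.
    """
    if group_size < 2:
        raise InvalidInputError("group_size must be at least 2")
    b = beliefs.pgg_other_contribution
    opts = []
    for c in _money_grid(endowment):
        share = (multiplier / group_size) * (c + (group_size - 1) * b)
        opts.append((c, Allocation(endowment - c + share, endowment - b + share)))
    return DecisionContext("PGG", b, tuple(opts))


def build_tg_truster_context(beliefs: BeliefConfig = BeliefConfig()) -> DecisionContext:
    """Truster transfer menu under the believed trustee return fraction."""
    rho = beliefs.tg_expected_return_fraction
    opts = []
    for t in _money_grid(1000):
        opts.append((t, Allocation(1000 - t + 3 * t * rho, 3 * t * (1 - rho))))
    return DecisionContext("TG_TRUSTER", round(rho, 6), tuple(opts))


def build_tg_trustee_contexts() -> list[DecisionContext]:
    """Strategy-method trustee menus, one per truster transfer 100..1000.

    Option labels are the returned percentage of the tripled amount (0, 10,
    ..., 100).  The trustee holds no own endowment; the truster's payoff
    includes the kept ``1000 - t``.
    """
    contexts = []
    for t in range(100, 1001, 100):
        opts = []
        for pct in range(0, 101, 10):
            rho = pct / 100.0
            opts.append((pct, Allocation(3 * t * (1 - rho), 1000 - t + 3 * t * rho)))
        contexts.append(DecisionContext("TG_TRUSTEE", float(t), tuple(opts)))
    return contexts


def build_ug_proposer_context(
    beliefs: BeliefConfig = BeliefConfig(), endowment: float = 1500
) -> DecisionContext:
    """Proposer offer menu over 0..1500 in JPY 100 steps.

    In ``rejection_belief`` mode each option carries the probability that a
    softmax responder with the configured preference parameters accepts it.
    """
    opts = tuple((o, Allocation(endowment - o, o)) for o in _money_grid(endowment))
    probs = None
    if beliefs.ug_proposer_mode == "rejection_belief":
        from .preferences import ug_acceptance_probability

        params = beliefs.ug_proposer_rejection_params
        probs = tuple(
            ug_acceptance_probability(o, params, endowment=endowment) for o, _ in opts
        )
    return DecisionContext("UG_PROPOSER", float(endowment), opts, probs)


def build_ug_responder_contexts(endowment: float = 1500) -> list[DecisionContext]:
    """Binary accept/reject contexts, one per offer 0..1500; rejection pays (0, 0)."""
    contexts = []
    for o in _money_grid(endowment):
        opts = (
            ("accept", Allocation(o, endowment - o)),
            ("reject", Allocation(0, 0)),
        )
        contexts.append(DecisionContext("UG_RESPONDER", float(o), opts))
    return contexts


def build_schedule(
    beliefs: BeliefConfig = BeliefConfig(),
    dg_endowments: Sequence[int] = DEFAULT_DG_ENDOWMENTS,
) -> list[DecisionContext]:
    """The full 37-decision session: 7 DG + PDG + PGG + truster + 10 trustee
    + proposer + 16 responder contexts, in that order."""
    return (
        build_dg_contexts(dg_endowments)
        + [build_pdg_context(beliefs)]
        + [build_pgg_context(beliefs)]
        + [build_tg_truster_context(beliefs)]
        + build_tg_trustee_contexts()
        + [build_ug_proposer_context(beliefs)]
        + build_ug_responder_contexts()
    )


# ---------------------------------------------------------------------------
# serialization


def contexts_to_frame(contexts: Iterable[DecisionContext]) -> pd.DataFrame:
    """Long-format table: one row per (context, option)."""
    rows = []
    for ctx in contexts:
        probs = ctx.accept_probs or [None] * len(ctx.options)
        for (lab, alloc), p in zip(ctx.options, probs):
            rows.append(
                {
                    "game": ctx.game,
                    "context_param": ctx.context_param,
                    "option_label": lab,
                    "x": alloc.x,
                    "y": alloc.y,
                    **({"accept_prob": p} if p is not None else {}),
                }
            )
    return pd.DataFrame(rows)


def _parse_label(raw) -> Label:
    try:
        f = float(raw)
    except (TypeError, ValueError):
        return str(raw)
    if f != int(f):
        raise DataError(f"non-integer option label {raw!r}")
    return int(f)


def contexts_from_frame(frame: pd.DataFrame) -> list[DecisionContext]:
    """Inverse of :func:`contexts_to_frame`; option order follows row order."""
    required = {"game", "context_param", "option_label", "x", "y"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"context table is missing columns: {sorted(missing)}")
    contexts = []
    for (game, param), grp in frame.groupby(["game", "context_param"], sort=False):
        opts = tuple(
            (_parse_label(r.option_label), Allocation(float(r.x), float(r.y)))
            for r in grp.itertuples()
        )
        probs = None
        if "accept_prob" in grp.columns and grp["accept_prob"].notna().all():
            probs = tuple(float(p) for p in grp["accept_prob"])
        contexts.append(DecisionContext(str(game), float(param), opts, probs))
    return contexts
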