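"""Inequity-aversion utility, softmax choice rule and the joint likelihood.

The model scores an allocation (x, y) — self payoff x, other payoff y — by

    U(x, y) = x - alpha * max((x + y)/2 - x, 0) - beta * max(x - (x + y)/2, 0)

where ``alpha`` (disadvantageous inequity aversion, DIA) penalises falling
behind the other and ``beta`` (advantageous inequity aversion, AIA) penalises
being ahead; at the equal split both penalty terms vanish.  Choices within a
context follow a softmax with inverse temperature ``lam``:

    P(choose i) = exp(lam * U_i) / sum_j exp(lam * U_j)

``lam = 0`` is uniform random choice; large ``lam`` approaches utility
maximisation.  All payoffs are rescaled to kJPY (divided by 1000) before
entering the softmax, so a single O(1) ``lam`` is comparable across games;
:func:`utility` itself works on whatever scale its allocation carries.

Because U is linear in (alpha, beta), the whole 37-context session likelihood
reduces to a few dense-array operations; :class:`CompiledSchedule` precomputes
the coefficient arrays once and evaluates the joint log-likelihood for many
parameter vectors (MCMC chains, grid nodes, simulated cohorts) at a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InvalidInputError
from .games import Allocation, DecisionContext, Label

__all__ = [
    "PAYOFF_SCALE",
    "PreferenceParams",
    "ChoiceRecord",
    "utility",
    "context_utilities",
    "choice_probabilities",
    "deterministic_choice",
    "log_likelihood",
    "ug_acceptance_probability",
    "CompiledSchedule",
    "records_to_frame",
    "records_from_frame",
]

#: kJPY per JPY — payoff rescaling applied before the softmax.
PAYOFF_SCALE = 1e-3


@dataclass(frozen=True)
class PreferenceParams:
    """(alpha, beta, lam): DIA weight, AIA weight, softmax inverse temperature.

    alpha and beta are unconstrained reals (no Fehr–Schmidt sign or ordering
    constraint is imposed at the likelihood level); lam must be >= 0.
    """

    alpha: float
    beta: float
    lam: float

    def __post_init__(self):
        if not all(map(math.isfinite, (self.alpha, self.beta, self.lam))):
            raise InvalidInputError(f"parameters must be finite, got {self}")
        if self.lam < 0:
            raise InvalidInputError(f"lam must be non-negative, got {self.lam}")


@dataclass(frozen=True)
class ChoiceRecord:
    """One observed decision, referencing its context by (game, context_param)."""

    participant_id: str
    game: str
    context_param: float
    chosen_label: Label


def utility(alloc: Allocation, params: PreferenceParams, scale: float = 1.0) -> float:
    """Inequity-aversion utility of one allocation (on ``scale`` × JPY units)."""
    x, y = alloc.x * scale, alloc.y * scale
    mean = (x + y) / 2.0
    return x - params.alpha * max(mean - x, 0.0) - params.beta * max(x - mean, 0.0)


def context_utilities(
    context: DecisionContext, params: PreferenceParams, scale: float = PAYOFF_SCALE
) -> np.ndarray:
    """Utilities of every option, in option order.

    For expected-value menus (UG proposer under rejection beliefs) each
    utility is weighted by the option's acceptance probability; the rejected
    outcome contributes 0 because U(0, 0) = 0 for all parameter values.
    """
    u = np.array([utility(a, params, scale) for _, a in context.options])
    if context.accept_probs is not None:
        u = u * np.asarray(context.accept_probs)
    return u


def choice_probabilities(
    context: DecisionContext, params: PreferenceParams, scale: float = PAYOFF_SCALE
) -> np.ndarray:
    """Softmax choice probabilities over the context's options.

    Max-subtraction keeps the exponentials bounded, so probabilities stay
    finite for arbitrarily peaked lam * U.
    """
    z = params.lam * context_utilities(context, params, scale)
    z -= z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def deterministic_choice(
    context: DecisionContext, params: PreferenceParams, scale: float = PAYOFF_SCALE
) -> Label:
    """The utility-maximising option label (lam → ∞ limit); ties go to the
    lowest label."""
    u = context_utilities(context, params, scale)
    best = u.max()
    tied = [lab for lab, ui in zip(context.labels, u) if ui >= best - 1e-12]
    return min(tied)


def ug_acceptance_probability(
    offer: float,
    params: PreferenceParams,
    endowment: float = 1500,
    scale: float = PAYOFF_SCALE,
) -> float:
    """Probability that a softmax responder accepts ``offer`` out of ``endowment``."""
    u_acc = utility(Allocation(offer, endowment - offer), params, scale)
    # U(0,0) = 0: rejection utility
    return float(1.0 / (1.0 + np.exp(-params.lam * u_acc)))


def log_likelihood(
    records: Iterable[ChoiceRecord],
    params: PreferenceParams,
    contexts: Sequence[DecisionContext],
    scale: float = PAYOFF_SCALE,
) -> float:
    """Joint log-likelihood of a participant's decisions.

    Decisions are conditionally independent given the parameters; each record
    contributes the log softmax probability of its chosen option.
    """
    index = {c.key: c for c in contexts}
    total = 0.0
    for rec in records:
        key = (rec.game, round(float(rec.context_param), 6))
        ctx = index.get(key)
        if ctx is None:
            raise DataError(f"record references unknown context {key}")
        p = choice_probabilities(ctx, params, scale)
        try:
            i = ctx.labels.index(rec.chosen_label)
        except ValueError:
            raise DataError(
                f"chosen label {rec.chosen_label!r} not an option of context {key}"
            ) from None
        total += float(np.log(p[i]))
    return total


# ---------------------------------------------------------------------------
# vectorised likelihood over a fixed schedule


class CompiledSchedule:
    """Flattened coefficient arrays for fast repeated likelihood evaluation.

    Every option across all contexts occupies one slot in flat arrays holding
    its self payoff, disadvantage gap, advantage gap (all in kJPY) and its
    expected-value weight, so that for parameter vectors a, b the option
    utilities are ``w * (x - a*d - b*adv)`` — computed for a whole batch of
    parameter rows as one outer product.
    """

    def __init__(self, contexts: Sequence[DecisionContext], scale: float = PAYOFF_SCALE):
        self.contexts = list(contexts)
        self.scale = scale
        xs, dis, adv, w = [], [], [], []
        starts, sizes = [], []
        self._key_to_ctx: dict = {}
        self._flat_index: dict = {}
        pos = 0
        for ci, ctx in enumerate(self.contexts):
            key = ctx.key
            if key in self._key_to_ctx:
                raise InvalidInputError(f"duplicate context key {key} in schedule")
            self._key_to_ctx[key] = ci
            starts.append(pos)
            sizes.append(len(ctx.options))
            probs = ctx.accept_probs or (1.0,) * len(ctx.options)
            for (lab, alloc), p in zip(ctx.options, probs):
                x, y = alloc.x * scale, alloc.y * scale
                mean = (x + y) / 2.0
                xs.append(x)
                dis.append(max(mean - x, 0.0))
                adv.append(max(x - mean, 0.0))
                w.append(p)
                self._flat_index[(key, lab)] = pos
                pos += 1
        self.x = np.asarray(xs)
        self.d = np.asarray(dis)
        self.a = np.asarray(adv)
        self.w = np.asarray(w)
        self.starts = np.asarray(starts, dtype=np.intp)
        self.sizes = np.asarray(sizes, dtype=np.intp)
        self.n_contexts = len(self.contexts)
        self.n_options = pos
        #: context index owning each flat option slot
        self.ctx_of_option = np.repeat(
            np.arange(self.n_contexts, dtype=np.intp), self.sizes
        )

    # -- encoding ------------------------------------------------------------

    def encode_records(self, records: Iterable[ChoiceRecord]) -> np.ndarray:
        """Flat option indices of a participant's decisions, in record order.

        A context may appear any number of times (or not at all); each record
        contributes one likelihood term.
        """
        flat = []
        for rec in records:
            key = (rec.game, round(float(rec.context_param), 6))
            if key not in self._key_to_ctx:
                raise DataError(f"record references unknown context {key}")
            idx = self._flat_index.get((key, rec.chosen_label))
            if idx is None:
                raise DataError(
                    f"chosen label {rec.chosen_label!r} not an option of context {key}"
                )
            flat.append(idx)
        return np.asarray(flat, dtype=np.intp)

    def encode_cohort(self, behaviour: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        """Encode a long behaviour table into (ids, chosen-index matrix).

        Every participant must have the same number of decisions (the batched
        sampler advances them in lock-step); ragged cohorts should be fitted
        participant by participant instead.
        """
        from .games import _parse_label

        ids, rows = [], []
        for pid, grp in behaviour.groupby("participant_id", sort=True):
            recs = [
                ChoiceRecord(
                    str(pid),
                    r.game,
                    float(r.context_param),
                    _parse_label(r.chosen_label),
                )
                for r in grp.itertuples()
            ]
            ids.append(str(pid))
            rows.append(self.encode_records(recs))
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise DataError(
                f"participants have unequal decision counts {sorted(lengths)}; "
                "fit ragged cohorts one participant at a time"
            )
        return ids, np.asarray(rows)

    # -- evaluation ----------------------------------------------------------

    def utilities(self, alpha, beta) -> np.ndarray:
        """Option utilities, shape (batch, n_options), for parameter vectors."""
        alpha = np.atleast_1d(np.asarray(alpha, dtype=float))[:, None]
        beta = np.atleast_1d(np.asarray(beta, dtype=float))[:, None]
        return self.w * (self.x - alpha * self.d - beta * self.a)

    def log_likelihood(self, alpha, beta, lam, chosen: np.ndarray) -> np.ndarray:
        """Joint log-likelihood for a batch of (alpha, beta, lam) rows.

        ``chosen`` is (n_records,) or (batch, n_records) of flat option
        indices, one per decision; a single row is broadcast against the
        parameter batch.  Each record contributes ``z_chosen - logsumexp(z)``
        over its own context's options.
        """
        lam = np.atleast_1d(np.asarray(lam, dtype=float))[:, None]
        z = lam * self.utilities(alpha, beta)  # (batch, n_options)
        zmax = np.maximum.reduceat(z, self.starts, axis=1)
        zmax_full = np.repeat(zmax, self.sizes, axis=1)
        sums = np.add.reduceat(np.exp(z - zmax_full), self.starts, axis=1)
        logz = zmax + np.log(sums)  # (batch, n_contexts) per-context log norm
        chosen = np.atleast_2d(np.asarray(chosen, dtype=np.intp))
        if chosen.shape[0] == 1 and z.shape[0] > 1:
            chosen = np.broadcast_to(chosen, (z.shape[0], chosen.shape[1]))
        zc = np.take_along_axis(z, chosen, axis=1)
        norms = np.take_along_axis(logz, self.ctx_of_option[chosen], axis=1)
        return (zc - norms).sum(axis=1)


# ---------------------------------------------------------------------------
# behaviour-table serialization


def records_to_frame(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "game": [r.game for r in records],
            "context_param": [r.context_param for r in records],
            "chosen_label": [r.chosen_label for r in records],
        }
    )


def records_from_frame(frame: pd.DataFrame) -> list[ChoiceRecord]:
    required = {"participant_id", "game", "context_param", "chosen_label"}
    missing = required - set(frame.columns)
    if missing:
        raise DataError(f"behaviour table is missing columns: {sorted(missing)}")
    from .games import _parse_label

    return [
        ChoiceRecord(
            str(r.participant_id),
            str(r.game),
            float(r.context_param),
            _parse_label(r.chosen_label),
        )
        for r in frame.itertuples()
    ]
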