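"""Incidence-tiered initial ranking and dynamic naive-Bayes re-ranking.

Before any finding is coded, candidate diagnoses are displayed grouped by
incidence tier (common, then uncommon, then rare) and, within each tier, in a
seeded uniform-random order.  Scores start as the incidence prior normalized
over the candidate set.

Once findings are coded the list re-orders by posterior support under a
naive-Bayes model: for diagnosis :math:`d` with annual incidence
:math:`\\pi_d` and coded findings :math:`f_1..f_k`,

.. math::

    \\mathrm{score}(d) \\propto \\pi_d \\prod_i L_i(d), \\qquad
    L_i(d) = \\begin{cases}
      p(f_i\\mid d)\\,/\\,p(f_i\\mid \\neg d) & f_i \\text{ coded present}\\\\
      (1-p(f_i\\mid d))\\,/\\,(1-p(f_i\\mid \\neg d)) & f_i \\text{ coded absent}\\\\
      1 & f_i \\text{ not associated with } d
    \\end{cases}

so both presence and absence are informative, uncoded findings are neutral,
and the final scores are invariant to coding order.  Accumulation is done in
log space to avoid underflow; scores are normalized to sum to 1 at read-out.

After the first coded finding the display order is purely score-descending;
ties are broken by the seeded initial (n_coded = 0) order, so the whole
trajectory is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .consultation import CodedFinding
from .errors import DomainError, ReferenceLookupError
from .evidence import DiagnosisEntry, EvidenceBase, IncidenceTier

__all__ = [
    "RankedItem",
    "RankedList",
    "initial_ranking",
    "posterior_scores",
    "update_ranking",
]


@dataclass(frozen=True)
class RankedItem:
    dx_id: str
    score: float  # normalized posterior support, in [0, 1]
    tier: IncidenceTier
    display_rank: int  # 1-based


@dataclass(frozen=True)
class RankedList:
    """The ordered suggestion list at one point in the consultation.

    ``initial_order`` is the n_coded = 0 display order (tier-grouped, seeded
    within-tier shuffle); it is the tie-break for all later re-rankings.
    ``log_scores`` carries the unnormalized log posterior per diagnosis so
    updates are incremental.
    """

    items: tuple[RankedItem, ...]
    seed: int
    n_coded: int
    initial_order: tuple[str, ...]
    log_scores: Mapping[str, float]

    def scores(self) -> dict[str, float]:
        return {item.dx_id: item.score for item in self.items}

    def order(self) -> tuple[str, ...]:
        return tuple(item.dx_id for item in self.items)


def _log_likelihood_increment(entry: DiagnosisEntry, coded: CodedFinding) -> float:
    """Log likelihood ratio the coded finding contributes for one diagnosis."""
    for assoc in entry.associations:
        if assoc.finding_id == coded.finding_id:
            if coded.present:
                return math.log(assoc.p_given_dx) - math.log(assoc.p_given_not_dx)
            return math.log1p(-assoc.p_given_dx) - math.log1p(-assoc.p_given_not_dx)
    return 0.0  # finding not associated with this diagnosis: neutral


def _normalize(log_scores: Mapping[str, float], order: Sequence[str]) -> dict[str, float]:
    logs = np.array([log_scores[dx] for dx in order], dtype=float)
    logs -= logs.max()
    w = np.exp(logs)
    w /= w.sum()
    return dict(zip(order, w))


def _initial_display_order(candidates: Sequence[DiagnosisEntry], seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    order: list[str] = []
    for tier in (IncidenceTier.COMMON, IncidenceTier.UNCOMMON, IncidenceTier.RARE):
        group = [e.dx_id for e in candidates if e.tier is tier]
        rng.shuffle(group)
        order.extend(group)
    return order


def _check_resolves(coded: CodedFinding, eb: Optional[EvidenceBase]) -> None:
    if eb is not None and coded.finding_id not in eb.findings:
        raise ReferenceLookupError(f"unknown finding {coded.finding_id!r}")


def initial_ranking(candidates: Sequence[DiagnosisEntry], seed: int) -> RankedList:
    """Tier-grouped, seeded initial suggestion list with incidence-prior scores."""
    if not candidates:
        raise DomainError("candidate list must be non-empty")
    by_id = {e.dx_id: e for e in candidates}
    order = _initial_display_order(candidates, seed)
    log_scores = {dx: math.log(by_id[dx].incidence) for dx in order}
    scores = _normalize(log_scores, order)
    items = tuple(
        RankedItem(dx_id=dx, score=scores[dx], tier=by_id[dx].tier, display_rank=rank)
        for rank, dx in enumerate(order, start=1)
    )
    return RankedList(
        items=items,
        seed=seed,
        n_coded=0,
        initial_order=tuple(order),
        log_scores=log_scores,
    )


def posterior_scores(
    candidates: Sequence[DiagnosisEntry],
    coded: Iterable[CodedFinding],
    *,
    eb: Optional[EvidenceBase] = None,
) -> dict[str, float]:
    """Normalized naive-Bayes posterior over the candidate set.

    With no coded findings this reduces to the normalized incidences.  When
    ``eb`` is given, every coded finding must resolve in it.
    """
    if not candidates:
        raise DomainError("candidate list must be non-empty")
    log_scores = {e.dx_id: math.log(e.incidence) for e in candidates}
    for cf in coded:
        _check_resolves(cf, eb)
        for entry in candidates:
            log_scores[entry.dx_id] += _log_likelihood_increment(entry, cf)
    return _normalize(log_scores, [e.dx_id for e in candidates])


def update_ranking(
    current: RankedList,
    candidates: Sequence[DiagnosisEntry],
    new_finding: CodedFinding,
    *,
    eb: Optional[EvidenceBase] = None,
) -> RankedList:
    """Incorporate one newly coded finding and re-rank score-descending.

    Incremental update is exactly equivalent to recomputing the posterior
    from scratch on the full coded set (the likelihood-ratio product
    commutes); ties keep the seeded initial order.
    """
    _check_resolves(new_finding, eb)
    by_id = {e.dx_id: e for e in candidates}
    missing = set(current.initial_order) - set(by_id)
    if missing:
        raise DomainError(f"candidates missing previously ranked diagnoses: {sorted(missing)}")
    log_scores = {
        dx: current.log_scores[dx] + _log_likelihood_increment(by_id[dx], new_finding)
        for dx in current.initial_order
    }
    initial_pos = {dx: i for i, dx in enumerate(current.initial_order)}
    order = sorted(log_scores, key=lambda dx: (-log_scores[dx], initial_pos[dx]))
    scores = _normalize(log_scores, order)
    items = tuple(
        RankedItem(dx_id=dx, score=scores[dx], tier=by_id[dx].tier, display_rank=rank)
        for rank, dx in enumerate(order, start=1)
    )
    return RankedList(
        items=items,
        seed=current.seed,
        n_coded=current.n_coded + 1,
        initial_order=current.initial_order,
        log_scores=log_scores,
    )
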