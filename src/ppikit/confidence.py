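"""Noisy-OR confidence scoring and 5-star categorisation.

Each detection platform i contributes an independent reliability score
S_i in [0, 1]; the per-release confidence is the noisy-OR combination

    P_new = 1 - prod_i (1 - S_i),

i.e. the probability that at least one platform's claim is correct under
independence. A prior-release score fuses in the same way,

    P = 1 - (1 - P_prev) * (1 - P_new),

so re-scoring is local: pairs new to the current release simply carry
P_prev = 0. The final score maps onto five fixed confidence tiers.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    EvidenceRecord,
    InputError,
    InteractionKey,
    ScoredInteraction,
    SourceTable,
)

#: Lower score bound (inclusive) of each star tier, highest first.
STAR_THRESHOLDS: tuple[tuple[int, float], ...] = (
    (5, 0.90),
    (4, 0.75),
    (3, 0.45),
    (2, 0.25),
    (1, 0.0),
)

STAR_LABELS = {
    1: "ultra-low",
    2: "low",
    3: "medium",
    4: "high",
    5: "ultra-high",
}


def _check_unit(p: float, what: str) -> float:
    if not 0.0 <= p <= 1.0:
        raise InputError(f"{what} outside [0, 1]: {p}")
    return p


def _clamp(p: float) -> float:
    # absorb float drift at the 1e-15 level
    return min(1.0, max(0.0, p))


def combine_platform_scores(scores: Sequence[float]) -> float:
    """Noisy-OR of per-platform scores: ``1 - prod(1 - s)``.

    Order-invariant, monotone in each score and in the number of scores;
    the empty combination is 0.
    """
    prod = 1.0
    for s in scores:
        _check_unit(s, "platform score")
        prod *= 1.0 - s
    return _clamp(1.0 - prod)


def combine_releases(p_prev: float, p_new: float) -> float:
    """Fuse the prior-release and current-release scores by noisy-OR."""
    _check_unit(p_prev, "prior score")
    _check_unit(p_new, "new score")
    return _clamp(1.0 - (1.0 - p_prev) * (1.0 - p_new))


def assign_star(p: float) -> int:
    """Map a final confidence score onto its 1..5 star tier."""
    _check_unit(p, "confidence score")
    for star, lo in STAR_THRESHOLDS:
        if p >= lo:
            return star
    return 1  # pragma: no cover - p >= 0 always matches the last tier


def score_database(
    tables: Iterable[SourceTable],
    prior: Optional[Mapping[InteractionKey, float]] = None,
) -> list[ScoredInteraction]:
    """Score every distinct pair across all source tables.

    Evidence is pooled per pair; duplicate claims from the *same* platform
    collapse to their maximum S_i (the product runs over platforms, so
    repeated rows from one platform must not inflate P). The prior maps
    pairs to their previous-release score, defaulting to 0.

    Returns one :class:`ScoredInteraction` per key, in deterministic order
    (descending final score, then key).
    """
    tables = list(tables)
    if not tables:
        raise InputError("no source tables given")
    prior = prior or {}
    # key -> platform -> max s_i, and key -> contributing sources
    by_key: dict[InteractionKey, dict[str, float]] = {}
    provenance: dict[InteractionKey, set[str]] = {}
    for table in tables:
        for rec in table.records:
            _check_unit(rec.s_i, f"score for {rec.key}")
            plats = by_key.setdefault(rec.key, {})
            if rec.s_i > plats.get(rec.platform, -1.0):
                plats[rec.platform] = rec.s_i
            provenance.setdefault(rec.key, set()).add(rec.source)
    out = []
    for key, plats in by_key.items():
        p_prev = _check_unit(prior.get(key, 0.0), f"prior for {key}")
        p_new = combine_platform_scores(list(plats.values()))
        p_final = combine_releases(p_prev, p_new)
        out.append(
            ScoredInteraction(
                key=key,
                p_prev=p_prev,
                p_new=p_new,
                p_final=p_final,
                star=assign_star(p_final),
                sources=frozenset(provenance[key]),
            )
        )
    # pairs present only in the prior (no new evidence) keep their old score
    for key, p_prev in prior.items():
        if key in by_key:
            continue
        p_prev = _check_unit(p_prev, f"prior for {key}")
        out.append(
            ScoredInteraction(
                key=key,
                p_prev=p_prev,
                p_new=0.0,
                p_final=_clamp(p_prev),
                star=assign_star(p_prev),
                sources=frozenset(),
            )
        )
    out.sort(key=lambda si: (-si.p_final, si.key))
    return out
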