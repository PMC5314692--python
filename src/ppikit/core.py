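"""Core domain types shared by every other module.

The toolkit's unit of data is an *unordered* protein pair. All readers,
scorers and evaluators canonicalise pairs through :func:`canonical_pair`
so that ``(x, y)`` and ``(y, x)`` always hash and compare equal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

log = logging.getLogger(__name__)

#: A canonical protein identifier (reviewed-accession-style token).
ProteinId = str


class InputError(ValueError):
    """Raised on any malformed or out-of-range input value."""


def _check_token(tok: str, what: str) -> str:
    if not tok or any(c.isspace() for c in tok):
        raise InputError(f"{what} must be a non-empty token without whitespace: {tok!r}")
    return tok


class InteractionKey(NamedTuple):
    """Canonical unordered protein pair: ``a <= b`` lexicographically."""

    a: ProteinId
    b: ProteinId

    @property
    def is_self(self) -> bool:
        """True for a self-interaction (both partners identical)."""
        return self.a == self.b

    @property
    def proteins(self) -> frozenset[ProteinId]:
        return frozenset((self.a, self.b))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.a}--{self.b}"


def canonical_pair(x: ProteinId, y: ProteinId) -> InteractionKey:
    """Return the canonical :class:`InteractionKey` for an unordered pair.

    Symmetric (``canonical_pair(x, y) == canonical_pair(y, x)``) and
    idempotent. Self-pairs are permitted; callers can filter on
    :attr:`InteractionKey.is_self`.
    """
    _check_token(x, "protein identifier")
    _check_token(y, "protein identifier")
    return InteractionKey(x, y) if x <= y else InteractionKey(y, x)


class EvidenceRecord(NamedTuple):
    """One source's claim about one pair, with a per-platform score in [0, 1]."""

    key: InteractionKey
    source: str
    platform: str
    s_i: float


@dataclass(frozen=True)
class ScoredInteraction:
    """A pair with its combined confidence and 5-star quality tier.

    ``p_final`` is the noisy-OR fusion of the prior-release score ``p_prev``
    and the current-release platform combination ``p_new``.
    """

    key: InteractionKey
    p_prev: float
    p_new: float
    p_final: float
    star: int
    sources: frozenset[str]


@dataclass(frozen=True)
class ReliabilityConfig:
    """Platform token -> reliability index in [0, 1].

    The reliability index expresses how much a detection platform is trusted
    to report direct physical interactions; unknown platforms fall back to
    ``fallback``. Values are configuration, not learned.
    """

    values: Mapping[str, float]
    fallback: float = 0.2

    def __post_init__(self) -> None:
        for plat, v in self.values.items():
            if not 0.0 <= v <= 1.0:
                raise InputError(f"reliability for {plat!r} outside [0, 1]: {v}")
        if not 0.0 <= self.fallback <= 1.0:
            raise InputError(f"fallback reliability outside [0, 1]: {self.fallback}")

    def get(self, platform: str) -> float:
        return self.values.get(platform, self.fallback)


#: Illustrative defaults: literature curation is trusted most for direct
#: physical binding, text mining / pure prediction least.
DEFAULT_RELIABILITY = ReliabilityConfig(
    values={
        "curated-literature": 0.9,
        "affinity-purification": 0.7,
        "yeast-two-hybrid": 0.5,
        "co-expression": 0.3,
        "text-mining": 0.2,
    },
    fallback=0.2,
)


@dataclass(frozen=True)
class GoldStandardSet:
    """Positive reference pairs (conserved co-expression style gold standard)."""

    pairs: frozenset[InteractionKey]
    name: str = "gold"


@dataclass(frozen=True)
class NegativeSet:
    """Curated non-interacting pairs used as negative reference."""

    pairs: frozenset[InteractionKey]
    name: str = "negative"


def check_disjoint(gold: GoldStandardSet, negatives: NegativeSet) -> int:
    """Warn (and return the count) if positive and negative references overlap."""
    shared = len(gold.pairs & negatives.pairs)
    if shared:
        log.warning(
            "gold standard %r and negative set %r share %d pairs", gold.name, negatives.name, shared
        )
    return shared


@dataclass(frozen=True)
class GeneSet:
    """A named curated gene collection (GMT line)."""

    name: str
    members: frozenset[ProteinId]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


class IdentifierMap:
    """Raw token -> canonical accession mapping with an unmapped tally.

    Lookup is exact on canonical accessions and case-insensitive on raw
    gene-symbol tokens. Absence is a value (``None``), never an error;
    misses are tallied in :attr:`unmapped` for reporting.
    """

    def __init__(self, raw_to_canonical: Mapping[str, ProteinId], dropped_ambiguous: int = 0):
        self._by_lower = {r.lower(): c for r, c in raw_to_canonical.items()}
        self._accessions = frozenset(raw_to_canonical.values())
        self.dropped_ambiguous = dropped_ambiguous
        self.unmapped: dict[str, int] = {}

    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, bool]], reviewed_only: bool = True
    ) -> "IdentifierMap":
        """Build from ``(raw_id, canonical, reviewed)`` rows.

        Raw tokens that map to more than one canonical accession are dropped
        (counted in ``dropped_ambiguous``): downstream identity must be
        one-to-one.
        """
        seen: dict[str, set[str]] = {}
        for raw, canon, reviewed in rows:
            if reviewed_only and not reviewed:
                continue
            seen.setdefault(raw.lower(), set()).add(canon)
        mapping = {r: next(iter(cs)) for r, cs in seen.items() if len(cs) == 1}
        dropped = sum(1 for cs in seen.values() if len(cs) > 1)
        if dropped:
            log.info("dropped %d ambiguous raw identifiers from mapping", dropped)
        return cls(mapping, dropped_ambiguous=dropped)

    def map(self, raw: str) -> Optional[ProteinId]:
        if raw in self._accessions:
            return raw
        hit = self._by_lower.get(raw.lower())
        if hit is None:
            self.unmapped[raw] = self.unmapped.get(raw, 0) + 1
        return hit

    @property
    def n_unmapped(self) -> int:
        return sum(self.unmapped.values())


def identity_map(proteins: Iterable[ProteinId]) -> IdentifierMap:
    """A mapping where every listed protein maps to itself (synthetic runs)."""
    return IdentifierMap({p: p for p in proteins})


@dataclass
class SourceTable:
    """All evidence records parsed from one source database dump."""

    name: str
    records: list[EvidenceRecord] = field(default_factory=list)
    n_unmapped: int = 0

    def keys(self) -> set[InteractionKey]:
        return {r.key for r in self.records}

    def __len__(self) -> int:
        return len(self.records)
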