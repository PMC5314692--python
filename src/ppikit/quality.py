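"""Stochastic-error, false-positive, functional-similarity and bias evaluation.

Four complementary views of interactome quality:

* **Gold-pair enrichment sampling** — repeatedly draw fixed-size random
  samples of database pairs and count their overlap with a positive
  reference set (conserved co-expression pairs); the overlap distribution's
  mean and spread characterise how enriched the database is in validated
  pairs. A *normalized sample size* scales the draw with database size so
  databases of different sizes are compared on the same slice.
* **False-positive ratio** — E = O / N, the fraction of database pairs that
  appear in a curated negative (non-interacting) reference.
* **Functional similarity** — per-tier samples of gene-pair GO similarity
  (information-content based Lin term similarity, best-match average,
  BP/MF mean), compared to random pairs by Welch's t-test.
* **Systematic-bias protein sets** — proteome proteins absent from the
  network, positive-reference proteins missed by the network, and top-k
  hub proteins; each set feeds a hypergeometric term-enrichment analysis
  with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    GoldStandardSet,
    InputError,
    InteractionKey,
    NegativeSet,
    ProteinId,
    ScoredInteraction,
)
from .ontology import AnnotationCorpus, gene_pair_gosim

__all__ = [
    "MpeDistribution",
    "mpe_distribution",
    "normalized_sample_size",
    "FalsePositiveReport",
    "false_positive_ratio",
    "score_auc",
    "gene_pair_gosim",
    "GoSimReport",
    "tier_gosim_test",
    "absent_protein_set",
    "missing_overlap_set",
    "hub_set",
    "enrichment",
]


# ---------------------------------------------------------------------------
# gold-pair enrichment sampling


@dataclass(frozen=True)
class MpeDistribution:
    """Distribution of gold-standard overlap counts over random samples."""

    sample_size: int
    n_samples: int
    overlaps: np.ndarray  # one overlap count per sample
    bin_edges: np.ndarray
    bin_counts: np.ndarray
    mean: float
    sd: float
    seed: int


def mpe_distribution(
    db: Iterable[InteractionKey],
    gold: GoldStandardSet,
    sample_size: int,
    n_samples: int,
    seed: int,
) -> MpeDistribution:
    """Sample ``n_samples`` sets of ``sample_size`` pairs (uniform, without
    replacement within a sample) and histogram their gold-set overlaps.

    Bins have width 1 when the expected overlap is small (< 50), otherwise
    Sturges' rule; reproducible for a fixed seed.
    """
    keys = sorted(set(db))
    n = len(keys)
    if sample_size > n:
        raise InputError(f"sample_size {sample_size} exceeds database size {n}")
    member = np.fromiter((k in gold.pairs for k in keys), dtype=bool, count=n)
    rng = np.random.default_rng(seed)
    overlaps = np.empty(n_samples, dtype=np.int64)
    for i in range(n_samples):
        idx = rng.choice(n, size=sample_size, replace=False)
        overlaps[i] = int(member[idx].sum())
    expected = sample_size * member.sum() / n
    if expected < 50:
        lo, hi = int(overlaps.min()), int(overlaps.max())
        edges = np.arange(lo, hi + 2) - 0.5
    else:
        edges = np.histogram_bin_edges(overlaps, bins="sturges")
    counts, edges = np.histogram(overlaps, bins=edges)
    return MpeDistribution(
        sample_size=sample_size,
        n_samples=n_samples,
        overlaps=overlaps,
        bin_edges=edges,
        bin_counts=counts,
        mean=float(overlaps.mean()),
        sd=float(overlaps.std(ddof=1)) if n_samples > 1 else 0.0,
        seed=seed,
    )


def normalized_sample_size(base_sample: int, size_ratio: float) -> int:
    """Scale a sampling size by the ratio between two database sizes.

    Databases of different size are compared against a fixed-size reference
    set, so the larger database is sampled proportionally more.
    """
    if size_ratio <= 0:
        raise InputError(f"size ratio must be positive: {size_ratio}")
    return int(round(base_sample * size_ratio))


# ---------------------------------------------------------------------------
# false positives and score AUC


@dataclass(frozen=True)
class FalsePositiveReport:
    """Overlap with the negative reference: E = O / N."""

    overlap: int
    db_size: int
    ratio: float


def false_positive_ratio(
    db: Iterable[InteractionKey], negatives: NegativeSet
) -> FalsePositiveReport:
    keys = set(db)
    if not keys:
        raise InputError("empty database")
    o = len(keys & negatives.pairs)
    return FalsePositiveReport(overlap=o, db_size=len(keys), ratio=o / len(keys))


def score_auc(
    scored: Sequence[ScoredInteraction],
    positives: GoldStandardSet,
    negatives: NegativeSet,
) -> float:
    """Rank-based AUC of the final score separating positive from negative
    reference pairs present in the scored set; ties contribute 1/2.

    Equivalent to the Mann-Whitney U statistic normalised by n+ * n-.
    """
    pos_scores = [si.p_final for si in scored if si.key in positives.pairs]
    neg_scores = [si.p_final for si in scored if si.key in negatives.pairs]
    if not pos_scores or not neg_scores:
        raise InputError("need at least one scored positive and one scored negative")
    all_scores = np.asarray(pos_scores + neg_scores, dtype=float)
    ranks = stats.rankdata(all_scores)  # average ranks handle ties
    n_pos, n_neg = len(pos_scores), len(neg_scores)
    r_pos = ranks[:n_pos].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# per-tier functional similarity


@dataclass
class GoSimReport:
    """Per-tier functional-similarity samples vs. a random-pair baseline."""

    tier_samples: dict[int, np.ndarray] = field(default_factory=dict)
    baseline: np.ndarray = field(default_factory=lambda: np.empty(0))
    tests: dict[int, tuple[float, float]] = field(default_factory=dict)  # tier -> (t, p)
    skipped: list[int] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def mean(self, tier: int) -> float:
        return float(self.tier_samples[tier].mean())


def tier_gosim_test(
    scored: Sequence[ScoredInteraction],
    corpus: AnnotationCorpus,
    tiers: Sequence[int] = (1, 2, 3, 4, 5),
    n_per_tier: int = 1000,
    seed: int = 0,
) -> GoSimReport:
    """Sample up to ``n_per_tier`` annotated pairs per star tier, score their
    functional similarity, and Welch-test each tier against an equal-size
    random-pair baseline drawn from the annotated gene universe.

    Tiers with fewer than ``n_per_tier`` eligible pairs are skipped with a
    warning. Unequal-variance (Welch) t-tests are used because tier
    variances differ by construction.
    """
    rng = np.random.default_rng(seed)
    annotated = corpus.genes()
    report = GoSimReport(
        metadata={
            "term_similarity": "lin",
            "gene_similarity": "best-match-average",
            "cross_namespace": "mean(BP, MF)",
            "n_per_tier": n_per_tier,
            "seed": seed,
        }
    )
    universe = sorted(annotated)
    if len(universe) < 2:
        raise InputError("fewer than two annotated genes in the corpus")
    base_pairs = rng.integers(0, len(universe), size=(n_per_tier, 2))
    baseline = []
    for i, j in base_pairs:
        if i == j:
            j = (j + 1) % len(universe)
        s = gene_pair_gosim(universe[i], universe[j], corpus)
        baseline.append(0.0 if s is None else s)
    report.baseline = np.asarray(baseline, dtype=float)

    by_tier: dict[int, list[ScoredInteraction]] = {t: [] for t in tiers}
    for si in scored:
        if si.star in by_tier and si.key.a in annotated and si.key.b in annotated:
            by_tier[si.star].append(si)
    for tier in tiers:
        cand = sorted(by_tier[tier], key=lambda si: si.key)
        if len(cand) < n_per_tier:
            warnings.warn(
                f"tier {tier}: only {len(cand)} annotated pairs, "
                f"fewer than requested {n_per_tier}; skipped",
                stacklevel=2,
            )
            report.skipped.append(tier)
            continue
        picks = rng.choice(len(cand), size=n_per_tier, replace=False)
        sims = []
        for idx in picks:
            key = cand[idx].key
            s = gene_pair_gosim(key.a, key.b, corpus)
            sims.append(0.0 if s is None else s)
        sample = np.asarray(sims, dtype=float)
        report.tier_samples[tier] = sample
        t, p = stats.ttest_ind(sample, report.baseline, equal_var=False)
        report.tests[tier] = (float(t), float(p))
    return report


# ---------------------------------------------------------------------------
# systematic-bias protein sets


def _proteins_of(pairs: Iterable[InteractionKey]) -> set[ProteinId]:
    out: set[ProteinId] = set()
    for k in pairs:
        out.add(k.a)
        out.add(k.b)
    return out


def absent_protein_set(
    db: Iterable[InteractionKey], reference_proteome: Iterable[ProteinId]
) -> set[ProteinId]:
    """Reviewed-proteome proteins that never appear in any database pair."""
    return set(reference_proteome) - _proteins_of(db)


def missing_overlap_set(
    db: Iterable[InteractionKey], gold: GoldStandardSet
) -> set[ProteinId]:
    """Proteins of the positive reference missed by the database overlap.

    Proteins appearing in gold pairs but not in any pair of db ∩ gold.
    """
    covered = _proteins_of(set(db) & gold.pairs)
    return _proteins_of(gold.pairs) - covered


def hub_set(db: Iterable[InteractionKey], k: int = 100) -> list[ProteinId]:
    """Top-k proteins by degree (distinct interaction partners).

    Ties break lexicographically for determinism; if the network has fewer
    than k proteins all are returned with a warning.
    """
    keys = set(db)
    if not keys:
        raise InputError("empty database")
    deg = degree_map(keys)
    ranked = sorted(deg, key=lambda p: (-deg[p], p))
    if k > len(ranked):
        warnings.warn(f"requested top-{k} hubs but only {len(ranked)} proteins", stacklevel=2)
        return ranked
    return ranked[:k]


def degree_map(db: Iterable[InteractionKey]) -> dict[ProteinId, int]:
    """Number of distinct interaction partners per protein (self counts once)."""
    adj: dict[ProteinId, set[ProteinId]] = {}
    for key in set(db):
        adj.setdefault(key.a, set()).add(key.b)
        adj.setdefault(key.b, set()).add(key.a)
    return {p: len(nb) for p, nb in adj.items()}


# ---------------------------------------------------------------------------
# term enrichment


def enrichment(
    gene_set: Iterable[ProteinId],
    background: Iterable[ProteinId],
    corpus: AnnotationCorpus,
    alpha: float = 0.05,
    namespaces: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of ``gene_set`` against ``background``.

    One-sided upper-tail p per term (propagated annotations), adjusted
    across all tested terms by Benjamini-Hochberg; rows sorted by adjusted
    p then term. Columns: term, namespace, set_count, background_count,
    p_value, adjusted_p, significant.
    """
    from statsmodels.stats.multitest import multipletests

    genes = set(gene_set)
    bg = set(background)
    if not genes:
        raise InputError("empty gene set")
    if not genes <= bg:
        raise InputError("gene set must be a subset of the background")
    nss = list(namespaces) if namespaces else list(corpus.annotations)
    rows = []
    m = len(bg)
    n = len(genes)
    for ns in nss:
        ann = corpus.annotations.get(ns, {})
        term_bg: dict[str, int] = {}
        term_set: dict[str, int] = {}
        for g in bg:
            for t in ann.get(g, ()):  # propagated terms
                term_bg[t] = term_bg.get(t, 0) + 1
                if g in genes:
                    term_set[t] = term_set.get(t, 0) + 1
        for term, bg_count in sorted(term_bg.items()):
            k = term_set.get(term, 0)
            p = float(stats.hypergeom.sf(k - 1, m, bg_count, n))
            rows.append((term, ns, k, bg_count, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "namespace", "set_count", "background_count", "p_value"]
    )
    if len(df):
        _, adj, _, _ = multipletests(df["p_value"].to_numpy(), method="fdr_bh")
        df["adjusted_p"] = np.maximum(adj, df["p_value"].to_numpy())
    else:
        df["adjusted_p"] = pd.Series(dtype=float)
    df["significant"] = df["adjusted_p"] < alpha
    return df.sort_values(["adjusted_p", "term"], kind="stable").reset_index(drop=True)
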