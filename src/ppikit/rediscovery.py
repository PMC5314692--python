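"""Gene-set rediscovery benchmark: hidden-gene retrieval by network expansion.

Each curated gene set is split at random into a seeded set S and a hidden
set H. The one-step expansion G of S in a PPI network contains every gene
directly interacting with a member of S (S itself excluded). Retrieval
*sensitivity* is |H ∩ G| / |H|. Because bigger databases inflate G, the
*rediscovery factor*

    alpha = |H ∩ G| / |G| * f,       f = |G_db| / |G_reference|,

rescales precision by the expansion-size ratio f against a reference
database, so a database cannot win simply by predicting everything:
uniform G inflation cancels out of alpha exactly.

The benchmark is paired: within a replicate every database sees the same
(S, H) partition, which is what makes the per-database sensitivities
comparable with a paired t-test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .core import GeneSet, InputError, InteractionKey, ProteinId


def partition_gene_set(
    gs: GeneSet, hidden_fraction: float = 0.5, seed: int = 0
) -> tuple[frozenset[ProteinId], frozenset[ProteinId]]:
    """Random disjoint exhaustive split of a gene set into (seeded, hidden).

    |H| = round(hidden_fraction * |gs|), clamped so both parts stay
    non-empty; reproducible for a fixed seed.
    """
    if len(gs) < 2:
        raise InputError(f"gene set {gs.name!r} needs >= 2 members to partition")
    if not 0.0 < hidden_fraction < 1.0:
        raise InputError(f"hidden_fraction must be in (0, 1): {hidden_fraction}")
    members = sorted(gs.members)
    n_hidden = int(round(hidden_fraction * len(members)))
    n_hidden = min(max(n_hidden, 1), len(members) - 1)
    rng = np.random.default_rng(seed)
    hidden_idx = rng.choice(len(members), size=n_hidden, replace=False)
    hidden = frozenset(members[i] for i in hidden_idx)
    seeded = frozenset(members) - hidden
    return seeded, hidden


def _adjacency(db: Iterable[InteractionKey]) -> dict[ProteinId, set[ProteinId]]:
    adj: dict[ProteinId, set[ProteinId]] = {}
    for key in db:
        adj.setdefault(key.a, set()).add(key.b)
        adj.setdefault(key.b, set()).add(key.a)
    return adj


def one_step_expansion(
    seeded: Iterable[ProteinId], db: Iterable[InteractionKey]
) -> frozenset[ProteinId]:
    """All proteins directly adjacent to the seeded set, seeded genes excluded."""
    s = set(seeded)
    adj = _adjacency(db)
    out: set[ProteinId] = set()
    for g in s:
        out |= adj.get(g, set())
    return frozenset(out - s)


def sensitivity(hidden: Iterable[ProteinId], expanded: Iterable[ProteinId]) -> float:
    """Fraction of hidden genes recovered by the expansion: |H∩G| / |H|."""
    h = set(hidden)
    if not h:
        raise InputError("hidden set is empty")
    return len(h & set(expanded)) / len(h)


def expansion_factor(
    g_db: Iterable[ProteinId], g_ref: Iterable[ProteinId]
) -> Optional[float]:
    """Expansion-size ratio f = |G_db| / |G_reference|.

    1 when the database under test is the reference itself; ``None`` (an
    undefined marker) when the reference expansion is empty.
    """
    n_ref = len(set(g_ref))
    if n_ref == 0:
        return None
    return len(set(g_db)) / n_ref


def rediscovery_alpha(
    hidden: Iterable[ProteinId], expanded: Iterable[ProteinId], f: float
) -> float:
    """Rediscovery factor alpha = |H∩G| / |G| * f (0 when G is empty)."""
    if f < 0:
        raise InputError(f"expansion factor must be nonnegative: {f}")
    g = set(expanded)
    if not g:
        return 0.0
    return len(set(hidden) & g) / len(g) * f


@dataclass(frozen=True)
class RediscoveryResult:
    """One gene set x one replicate x one database."""

    set_name: str
    replicate: int
    db_name: str
    n_seeded: int
    n_hidden: int
    n_expanded: int
    n_hit: int
    sensitivity: float
    f: Optional[float]
    alpha: Optional[float]
    seed: int


@dataclass
class BenchmarkSummary:
    """Aggregates over gene sets x replicates, plus paired tests."""

    results: list[RediscoveryResult]
    mean_sensitivity: dict[str, float]
    mean_alpha: dict[str, float]
    paired_tests: dict[tuple[str, str], tuple[float, float]]  # (t, p) on sensitivities
    hidden_fraction: float
    reps: int


def run_benchmark(
    gene_sets: Sequence[GeneSet],
    dbs: Mapping[str, Iterable[InteractionKey]],
    reference_db_name: str,
    reps: int = 50,
    min_set_size: int = 10,
    hidden_fraction: float = 0.5,
    seed: int = 0,
) -> BenchmarkSummary:
    """Run the paired rediscovery benchmark over all gene sets and databases.

    Gene sets below ``min_set_size`` are dropped. Every replicate draws one
    (S, H) partition per gene set and evaluates *all* databases on it, so
    the per-database sensitivity vectors are paired observation-for-
    observation; the summary reports their means and a paired t-test for
    every database pair.
    """
    if reference_db_name not in dbs:
        raise InputError(f"reference database {reference_db_name!r} not among inputs")
    sets = [gs for gs in gene_sets if len(gs) >= min_set_size]
    db_keys = {name: set(keys) for name, keys in dbs.items()}
    root = np.random.default_rng(seed)
    results: list[RediscoveryResult] = []
    sens_vectors: dict[str, list[float]] = {name: [] for name in db_keys}
    alpha_vectors: dict[str, list[float]] = {name: [] for name in db_keys}
    for gs in sets:
        for rep in range(reps):
            part_seed = int(root.integers(0, 2**31 - 1))
            seeded, hidden = partition_gene_set(gs, hidden_fraction, seed=part_seed)
            g_ref = one_step_expansion(seeded, db_keys[reference_db_name])
            for name, keys in db_keys.items():
                g = one_step_expansion(seeded, keys)
                f = 1.0 if name == reference_db_name else expansion_factor(g, g_ref)
                alpha = rediscovery_alpha(hidden, g, f) if f is not None else None
                sens = sensitivity(hidden, g)
                results.append(
                    RediscoveryResult(
                        set_name=gs.name,
                        replicate=rep,
                        db_name=name,
                        n_seeded=len(seeded),
                        n_hidden=len(hidden),
                        n_expanded=len(g),
                        n_hit=len(set(hidden) & g),
                        sensitivity=sens,
                        f=f,
                        alpha=alpha,
                        seed=part_seed,
                    )
                )
                sens_vectors[name].append(sens)
                alpha_vectors[name].append(alpha if alpha is not None else math.nan)
    paired: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b in itertools.combinations(sorted(db_keys), 2):
        va, vb = np.asarray(sens_vectors[a]), np.asarray(sens_vectors[b])
        if len(va) >= 2 and not np.allclose(va, vb):
            t, p = stats.ttest_rel(va, vb)
            paired[(a, b)] = (float(t), float(p))
        else:
            paired[(a, b)] = (0.0, 1.0)
    return BenchmarkSummary(
        results=results,
        mean_sensitivity={n: float(np.mean(v)) if v else math.nan for n, v in sens_vectors.items()},
        mean_alpha={n: float(np.nanmean(v)) if v else math.nan for n, v in alpha_vectors.items()},
        paired_tests=paired,
        hidden_fraction=hidden_fraction,
        reps=reps,
    )
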