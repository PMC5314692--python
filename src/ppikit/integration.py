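"""Merging scored sources into one interactome and cross-source redundancy.

The integrated interactome is the union of all per-source pair sets, each
pair annotated with the sources that claim it. Redundancy between sources
i and j is summarised by the coverage-overlap ratio

    r_ij = 100 * O_ij / N_i   (percent),

where O_ij is the pair-overlap count and N_i the row source's size, so the
matrix is deliberately asymmetric: r_ij * N_i == r_ji * N_j == 100 * O_ij.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GoldStandardSet, InteractionKey, SourceTable


def merge_sources(tables: Iterable[SourceTable]) -> dict[InteractionKey, frozenset[str]]:
    """Union all source pair sets; each key maps to its contributing sources."""
    prov: dict[InteractionKey, set[str]] = {}
    for table in tables:
        for key in table.keys():
            prov.setdefault(key, set()).add(table.name)
    return {k: frozenset(v) for k, v in prov.items()}


@dataclass(frozen=True)
class OverlapMatrix:
    """Pairwise coverage-overlap percentages between sources.

    ``ratios[i, j]`` is the percent of source i's pairs also present in
    source j; NaN marks ratios undefined because source i is empty.
    """

    sources: tuple[str, ...]
    sizes: tuple[int, ...]
    counts: np.ndarray  # symmetric integer overlap counts O_ij
    ratios: np.ndarray  # row-normalised percentages, NaN where undefined

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            np.round(self.ratios, 2), index=list(self.sources), columns=list(self.sources)
        )


def overlap_ratio_matrix(tables: Sequence[SourceTable]) -> OverlapMatrix:
    """Compute the full source-by-source coverage-overlap matrix.

    Counts are exact set intersections; ratios are percentages of the row
    source's size, reported to two decimals by :meth:`OverlapMatrix.to_frame`.
    An empty source yields NaN ratios in its row and column rather than a
    division by zero.
    """
    names = tuple(t.name for t in tables)
    keysets = [t.keys() for t in tables]
    sizes = tuple(len(ks) for ks in keysets)
    n = len(tables)
    counts = np.zeros((n, n), dtype=np.int64)
    ratios = np.full((n, n), math.nan)
    for i in range(n):
        for j in range(i, n):
            o = len(keysets[i] & keysets[j])
            counts[i, j] = counts[j, i] = o
    for i in range(n):
        if sizes[i] == 0:
            continue
        ratios[i, :] = 100.0 * counts[i, :] / sizes[i]
    return OverlapMatrix(sources=names, sizes=sizes, counts=counts, ratios=ratios)


def q_score(db: Iterable[InteractionKey], gold: GoldStandardSet) -> int:
    """Global quality score: overlap count between the database and the
    positive reference pair set."""
    return len(set(db) & gold.pairs)
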