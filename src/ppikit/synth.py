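"""Seeded generators for every input the toolkit consumes.

The generators emulate the structure of a multi-source interactome build:
a scale-free ground-truth network; several overlapping evidence sources,
each reporting a fraction of the truth plus platform-specific noise at a
platform-specific reliability; a gold standard embedded in the truth; a
negative set partially overlapping the observed network; a small two-
namespace ontology whose leaf terms are shared preferentially by
interacting genes; and curated-style gene sets drawn from network
neighborhoods so that rediscovery is non-trivial.

Everything is bit-reproducible under :class:`SynthConfig.seed`; each
generator derives its own stream so stages are independently stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from ._seeds import stage_rng
from .core import (
    DEFAULT_RELIABILITY,
    EvidenceRecord,
    GeneSet,
    GoldStandardSet,
    InputError,
    InteractionKey,
    NegativeSet,
    ProteinId,
    ReliabilityConfig,
    SourceTable,
    canonical_pair,
)
from .ontology import NAMESPACES, AnnotationCorpus


@dataclass(frozen=True)
class SourceSpec:
    """One emulated evidence source: its platform, truth coverage and noise.

    ``noise_fraction`` is relative to the source's covered-truth count, so
    a text-mining-style source with noise 1.0 reports as many spurious
    pairs as real ones.
    """

    name: str
    platform: str
    coverage: float
    noise_fraction: float


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a full synthetic run."""

    n_proteins: int = 1000
    n_truth_edges: int = 5000
    sources: tuple[SourceSpec, ...] = (
        SourceSpec("litdb", "curated-literature", coverage=0.12, noise_fraction=0.05),
        SourceSpec("apdb", "affinity-purification", coverage=0.35, noise_fraction=0.15),
        SourceSpec("y2hdb", "yeast-two-hybrid", coverage=0.40, noise_fraction=0.30),
        SourceSpec("coexdb", "co-expression", coverage=0.50, noise_fraction=0.50),
        SourceSpec("textdb", "text-mining", coverage=0.60, noise_fraction=1.00),
    )
    reliability: ReliabilityConfig = DEFAULT_RELIABILITY
    score_jitter: float = 0.03
    gold_coverage: float = 0.20
    n_negatives: int = 1000
    negative_contamination: float = 0.02
    negative_observed_fraction: float = 0.50
    ontology_depth: int = 3
    ontology_branching: int = 3
    annotation_share_prob: float = 0.70
    extra_annotation_prob: float = 0.30
    n_gene_sets: int = 30
    gene_set_size_min: int = 10
    gene_set_size_max: int = 20
    topology: str = "preferential-attachment"  # or "erdos-renyi"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (
            self.gold_coverage,
            self.negative_contamination,
            self.negative_observed_fraction,
            self.annotation_share_prob,
            self.extra_annotation_prob,
        ):
            if not 0.0 <= frac <= 1.0:
                raise InputError(f"fraction outside [0, 1]: {frac}")
        if self.n_proteins < 2 or self.n_truth_edges < 1:
            raise InputError("need at least 2 proteins and 1 truth edge")


def _protein(i: int) -> ProteinId:
    return f"P{i:05d}"


def protein_universe(cfg: SynthConfig) -> list[ProteinId]:
    return [_protein(i) for i in range(cfg.n_proteins)]


# ---------------------------------------------------------------------------
# truth network


def synth_truth_network(cfg: SynthConfig) -> set[InteractionKey]:
    """Connected scale-free (preferential-attachment) truth network with an
    exact edge count; Erdős–Rényi style attachment available as an option."""
    n, m = cfg.n_proteins, cfg.n_truth_edges
    max_edges = n * (n - 1) // 2
    if m < n - 1 or m > max_edges:
        raise InputError(f"cannot place {m} edges on {n} nodes (need {n - 1}..{max_edges})")
    rng = stage_rng(cfg.seed, "truth")
    preferential = cfg.topology == "preferential-attachment"
    edges: set[tuple[int, int]] = set()
    # endpoint multiset for preferential choice; uniform node list otherwise
    targets = [0]

    def add(u: int, v: int) -> bool:
        if u == v:
            return False
        e = (u, v) if u < v else (v, u)
        if e in edges:
            return False
        edges.add(e)
        targets.extend((u, v))
        return True

    for i in range(1, n):  # spanning tree keeps the network connected
        pool = targets if preferential else list(range(i))
        add(i, int(pool[rng.integers(0, len(pool))]))
    attempts = 0
    while len(edges) < m:
        pool = targets if preferential else list(range(n))
        u = int(pool[rng.integers(0, len(pool))])
        v = int(pool[rng.integers(0, len(pool))])
        if not add(u, v):
            attempts += 1
            if attempts > 50 * m:
                raise InputError("edge target infeasible for the requested density")
    return {canonical_pair(_protein(u), _protein(v)) for u, v in edges}


# ---------------------------------------------------------------------------
# evidence sources


def _random_nonedges(
    rng: np.random.Generator,
    n_proteins: int,
    count: int,
    forbidden: set[InteractionKey],
) -> set[InteractionKey]:
    out: set[InteractionKey] = set()
    attempts = 0
    while len(out) < count:
        i, j = rng.integers(0, n_proteins, size=2)
        if i == j:
            continue
        key = canonical_pair(_protein(int(i)), _protein(int(j)))
        if key in forbidden or key in out:
            attempts += 1
            if attempts > 100 * max(count, 1):
                raise InputError("cannot draw enough non-edges; network too dense")
            continue
        out.add(key)
    return out


def synth_sources(truth: set[InteractionKey], cfg: SynthConfig) -> list[SourceTable]:
    """Per-source evidence tables: a random coverage-fraction of truth edges
    plus platform noise, scored around the platform reliability."""
    truth_list = sorted(truth)
    tables = []
    for spec in cfg.sources:
        rng = stage_rng(cfg.seed, f"source:{spec.name}")
        n_cov = int(round(spec.coverage * len(truth_list)))
        idx = rng.choice(len(truth_list), size=n_cov, replace=False)
        covered = [truth_list[i] for i in idx]
        n_noise = int(round(spec.noise_fraction * n_cov))
        noise = _random_nonedges(rng, cfg.n_proteins, n_noise, forbidden=set(truth))
        base = cfg.reliability.get(spec.platform)
        table = SourceTable(name=spec.name)
        for key in covered + sorted(noise):
            s_i = float(np.clip(rng.normal(base, cfg.score_jitter), 0.01, 0.99))
            table.records.append(
                EvidenceRecord(key=key, source=spec.name, platform=spec.platform, s_i=s_i)
            )
        tables.append(table)
    return tables


# ---------------------------------------------------------------------------
# reference sets


def synth_gold(truth: set[InteractionKey], cfg: SynthConfig) -> GoldStandardSet:
    """Gold standard: a random subset of the truth at the configured coverage."""
    rng = stage_rng(cfg.seed, "gold")
    truth_list = sorted(truth)
    n = int(round(cfg.gold_coverage * len(truth_list)))
    if n > len(truth_list):
        raise InputError("gold coverage exceeds available truth pairs")
    idx = rng.choice(len(truth_list), size=n, replace=False)
    return GoldStandardSet(pairs=frozenset(truth_list[i] for i in idx), name="synthetic-gold")


def synth_negatives(
    truth: set[InteractionKey],
    cfg: SynthConfig,
    observed: Optional[Iterable[InteractionKey]] = None,
) -> NegativeSet:
    """Negative reference: mostly non-edges, a configured slice of which is
    drawn from *observed* (reported but not true) pairs so the negative set
    partially overlaps the integrated network, plus a small contamination
    of genuine truth pairs (curated negative sets are imperfect too)."""
    rng = stage_rng(cfg.seed, "negatives")
    n = cfg.n_negatives
    n_cont = int(round(cfg.negative_contamination * n))
    truth_list = sorted(truth)
    if n_cont > len(truth_list):
        raise InputError("contamination exceeds available truth pairs")
    picked: set[InteractionKey] = set()
    if n_cont:
        idx = rng.choice(len(truth_list), size=n_cont, replace=False)
        picked |= {truth_list[i] for i in idx}
    observed_nonedges = sorted(set(observed or ()) - truth)
    n_obs = min(int(round(cfg.negative_observed_fraction * n)), len(observed_nonedges))
    if n_obs:
        idx = rng.choice(len(observed_nonedges), size=n_obs, replace=False)
        picked |= {observed_nonedges[i] for i in idx}
    remaining = n - len(picked)
    if remaining > 0:
        picked |= _random_nonedges(
            rng, cfg.n_proteins, remaining, forbidden=truth | picked | set(observed or ())
        )
    return NegativeSet(pairs=frozenset(picked), name="synthetic-negative")


# ---------------------------------------------------------------------------
# ontology annotations


def synth_annotations(
    truth: set[InteractionKey], cfg: SynthConfig
) -> tuple[list[tuple[ProteinId, str]], list[tuple[str, str, str]]]:
    """Random tree DAG per namespace plus gene→leaf annotations.

    Every protein gets one primary leaf per namespace; for each truth edge,
    with probability ``annotation_share_prob`` the second endpoint also
    inherits the first endpoint's primary leaf, so interacting genes share
    informative terms far more often than random pairs do.
    Returns ``(gene_term_rows, dag_edge_rows)`` in the flat-file shapes.
    """
    rng = stage_rng(cfg.seed, "annotations")
    proteins = protein_universe(cfg)
    dag_edges: list[tuple[str, str, str]] = []
    leaves: dict[str, list[str]] = {}
    for ns in NAMESPACES:
        level = [f"{ns}:root"]
        counter = 0
        for _depth in range(cfg.ontology_depth):
            nxt = []
            for parent in level:
                for _ in range(cfg.ontology_branching):
                    term = f"{ns}:{counter:04d}"
                    counter += 1
                    dag_edges.append((term, parent, ns))
                    nxt.append(term)
            level = nxt
        leaves[ns] = level if level != [f"{ns}:root"] else [f"{ns}:root"]
    primary: dict[str, dict[ProteinId, str]] = {}
    annotations: dict[str, dict[ProteinId, set[str]]] = {}
    for ns in NAMESPACES:
        pool = leaves[ns]
        primary[ns] = {p: pool[int(rng.integers(0, len(pool)))] for p in proteins}
        annotations[ns] = {p: {primary[ns][p]} for p in proteins}
        for p in proteins:
            if rng.random() < cfg.extra_annotation_prob:
                annotations[ns][p].add(pool[int(rng.integers(0, len(pool)))])
    for key in sorted(truth):
        for ns in NAMESPACES:
            if rng.random() < cfg.annotation_share_prob:
                annotations[ns][key.b].add(primary[ns][key.a])
    gene_terms = [
        (p, t)
        for ns in NAMESPACES
        for p in proteins
        for t in sorted(annotations[ns][p])
    ]
    return gene_terms, dag_edges


def synth_corpus(truth: set[InteractionKey], cfg: SynthConfig) -> AnnotationCorpus:
    gene_terms, dag_edges = synth_annotations(truth, cfg)
    return AnnotationCorpus.build(gene_terms, dag_edges)


# ---------------------------------------------------------------------------
# gene sets


def synth_gene_sets(truth: set[InteractionKey], cfg: SynthConfig) -> list[GeneSet]:
    """Curated-style gene sets sampled from truth-network neighborhoods.

    Each set grows by breadth-first expansion from a random seed protein to
    a size drawn from the configured range, so its members are genuinely
    interconnected and one-step expansion can rediscover hidden members.
    """
    rng = stage_rng(cfg.seed, "gene-sets")
    adj: dict[ProteinId, list[ProteinId]] = {}
    for key in sorted(truth):
        adj.setdefault(key.a, []).append(key.b)
        adj.setdefault(key.b, []).append(key.a)
    nodes = sorted(adj)
    sets: list[GeneSet] = []
    guard = 0
    while len(sets) < cfg.n_gene_sets:
        guard += 1
        if guard > 100 * cfg.n_gene_sets:
            raise InputError("could not grow enough gene sets; network too sparse")
        target = int(rng.integers(cfg.gene_set_size_min, cfg.gene_set_size_max + 1))
        start = nodes[int(rng.integers(0, len(nodes)))]
        members: list[ProteinId] = [start]
        seen = {start}
        frontier = [start]
        while len(members) < target and frontier:
            nxt: list[ProteinId] = []
            for node in frontier:
                nbrs = [x for x in adj[node] if x not in seen]
                rng.shuffle(nbrs)
                for x in nbrs:
                    seen.add(x)
                    members.append(x)
                    nxt.append(x)
                    if len(members) >= target:
                        break
                if len(members) >= target:
                    break
            frontier = nxt
        if len(members) < cfg.gene_set_size_min:
            continue
        sets.append(GeneSet(name=f"SET{len(sets):03d}", members=frozenset(members)))
    return sets


# ---------------------------------------------------------------------------
# file emission


def generate_all(cfg: SynthConfig, outdir: str) -> dict[str, str]:
    """Generate every fixture and write it in the toolkit's flat formats.

    Returns a name → path map: truth, mapping, per-source tables, gold,
    negatives, annotations, dag, gene_sets.
    """
    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    truth = synth_truth_network(cfg)
    paths["truth"] = os.path.join(outdir, "truth_pairs.tsv")
    pio.write_pair_list(paths["truth"], truth)

    paths["mapping"] = os.path.join(outdir, "mapping.tsv")
    with open(paths["mapping"], "w", encoding="utf-8") as fh:
        fh.write("# raw_id\tcanonical\treviewed\n")
        for p in protein_universe(cfg):
            fh.write(f"{p}\t{p}\tY\n")

    tables = synth_sources(truth, cfg)
    observed: set[InteractionKey] = set()
    for table in tables:
        observed |= table.keys()
        path = os.path.join(outdir, f"source_{table.name}.tsv")
        paths[f"source:{table.name}"] = path
        with open(path, "w", encoding="utf-8") as fh:
            for rec in table.records:
                fh.write(f"{rec.key.a}\t{rec.key.b}\t{rec.platform}\t{rec.s_i:.6f}\n")

    gold = synth_gold(truth, cfg)
    paths["gold"] = os.path.join(outdir, "gold_pairs.tsv")
    pio.write_pair_list(paths["gold"], gold.pairs)

    negatives = synth_negatives(truth, cfg, observed=observed)
    paths["negatives"] = os.path.join(outdir, "negative_pairs.tsv")
    pio.write_pair_list(paths["negatives"], negatives.pairs)

    gene_terms, dag_edges = synth_annotations(truth, cfg)
    paths["annotations"] = os.path.join(outdir, "annotations.tsv")
    with open(paths["annotations"], "w", encoding="utf-8") as fh:
        for gene, term in gene_terms:
            fh.write(f"{gene}\t{term}\n")
    paths["dag"] = os.path.join(outdir, "ontology_dag.tsv")
    with open(paths["dag"], "w", encoding="utf-8") as fh:
        for child, parent, ns in dag_edges:
            fh.write(f"{child}\t{parent}\t{ns}\n")

    sets = synth_gene_sets(truth, cfg)
    paths["gene_sets"] = os.path.join(outdir, "gene_sets.gmt")
    with open(paths["gene_sets"], "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write(gs.name + "\tsynthetic neighborhood set\t" + "\t".join(sorted(gs.members)) + "\n")
    return paths
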