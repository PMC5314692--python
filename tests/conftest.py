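"""Shared fixtures: a small hand-built ontology and one full synthetic run.

The synthetic run is module-expensive, so it is session-scoped; tests must
treat its products as read-only.
"""

from __future__ import annotations

import pytest

from ppikit import confidence, synth
from ppikit.ontology import AnnotationCorpus


@pytest.fixture(scope="session")
def tiny_corpus() -> AnnotationCorpus:
    """Five informative BP terms, one root, five genes (one root-only).

    DAG:  root <- A <- {A1, A2};  root <- B <- B1
    Direct annotations: g1:{A1} g2:{A2} g3:{B1} g4:{A1} g5:{root}
    Propagated gene counts: root 5, A 3, A1 2, A2 1, B 1, B1 1.
    """
    dag = [
        ("A", "root", "BP"),
        ("B", "root", "BP"),
        ("A1", "A", "BP"),
        ("A2", "A", "BP"),
        ("B1", "B", "BP"),
    ]
    gaf = [("g1", "A1"), ("g2", "A2"), ("g3", "B1"), ("g4", "A1"), ("g5", "root")]
    return AnnotationCorpus.build(gaf, dag)


@pytest.fixture(scope="session")
def default_run():
    """One default-condition synthetic pipeline run, shared read-only."""
    cfg = synth.SynthConfig(seed=0)
    truth = synth.synth_truth_network(cfg)
    tables = synth.synth_sources(truth, cfg)
    scored = confidence.score_database(tables)
    gold = synth.synth_gold(truth, cfg)
    observed = set()
    for t in tables:
        observed |= t.keys()
    negatives = synth.synth_negatives(truth, cfg, observed=observed)
    return {
        "cfg": cfg,
        "truth": truth,
        "tables": tables,
        "scored": scored,
        "gold": gold,
        "negatives": negatives,
        "observed": observed,
    }
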