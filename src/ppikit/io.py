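"""Readers and writers for the toolkit's flat-file formats.

All tabular formats share one TSV dialect: UTF-8, tab-separated, no
quoting, lines starting with ``#`` are comments. This matches the flat
exports of typical interaction databases without vendor-specific parsing.

Formats
-------
mapping table       raw_id <TAB> canonical_accession <TAB> reviewed(Y/N)
source table        protein_a <TAB> protein_b [<TAB> platform [<TAB> score]]
pair list           protein_a <TAB> protein_b
gene sets           GMT: name <TAB> description <TAB> member...
annotations (GAF-lite)  gene <TAB> term
ontology DAG        child <TAB> parent <TAB> namespace(BP|MF)
scored interactions a, b, p_prev, p_new, p_final, star, sources (header row)
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional, Union

from .core import (
    EvidenceRecord,
    GeneSet,
    IdentifierMap,
    InputError,
    InteractionKey,
    ReliabilityConfig,
    ScoredInteraction,
    SourceTable,
    canonical_pair,
)
from .ontology import AnnotationCorpus

PathLike = Union[str, os.PathLike]


class ParseError(InputError):
    """Malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.path = str(path)
        self.lineno = lineno


def _rows(path: PathLike) -> Iterator[tuple[int, list[str]]]:
    """Yield (lineno, fields) for non-comment, non-blank lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_mapping(path: PathLike, reviewed_only: bool = True) -> IdentifierMap:
    """Load a raw-token -> canonical-accession mapping table."""
    rows = []
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "mapping row needs >= 2 columns")
        reviewed = fields[2].strip().upper() == "Y" if len(fields) >= 3 else True
        rows.append((fields[0].strip(), fields[1].strip(), reviewed))
    return IdentifierMap.from_rows(rows, reviewed_only=reviewed_only)


def read_source_table(
    path: PathLike,
    source_name: str,
    mapping: IdentifierMap,
    reliability: ReliabilityConfig,
) -> SourceTable:
    """Parse one source's evidence table into canonical records.

    Column 3 (optional) is the platform label, defaulting to the source
    name; column 4 (optional) is the per-platform score, defaulting to the
    configured reliability for the platform. Rows whose identifiers cannot
    be mapped are counted and skipped.
    """
    table = SourceTable(name=source_name)
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "source row needs >= 2 columns")
        a = mapping.map(fields[0].strip())
        b = mapping.map(fields[1].strip())
        if a is None or b is None:
            table.n_unmapped += 1
            continue
        platform = fields[2].strip() if len(fields) >= 3 and fields[2].strip() else source_name
        if len(fields) >= 4 and fields[3].strip():
            try:
                s_i = float(fields[3])
            except ValueError:
                raise ParseError(path, lineno, f"unparsable score {fields[3]!r}") from None
            if not 0.0 <= s_i <= 1.0:
                raise InputError(f"{path}:{lineno}: score outside [0, 1]: {s_i}")
        else:
            s_i = reliability.get(platform)
        table.records.append(
            EvidenceRecord(key=canonical_pair(a, b), source=source_name, platform=platform, s_i=s_i)
        )
    return table


def read_pair_list(path: PathLike, mapping: IdentifierMap) -> set[InteractionKey]:
    """Read a two-column pair list into a canonical key set (deduplicated)."""
    pairs: set[InteractionKey] = set()
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(path, lineno, "pair row needs >= 2 columns")
        a = mapping.map(fields[0].strip())
        b = mapping.map(fields[1].strip())
        if a is None or b is None:
            continue
        pairs.add(canonical_pair(a, b))
    return pairs


def read_gmt(path: PathLike) -> list[GeneSet]:
    """Read curated gene sets in GMT format (name, description, members...)."""
    sets = []
    for lineno, fields in _rows(path):
        if len(fields) < 3:
            raise ParseError(path, lineno, "GMT line needs name, description and >= 1 member")
        name = fields[0].strip()
        members = frozenset(f.strip() for f in fields[2:] if f.strip())
        sets.append(GeneSet(name=name, members=members))
    return sets


def read_annotations(gaf_path: PathLike, dag_path: PathLike) -> AnnotationCorpus:
    """Load gene annotations plus the term DAG and propagate to ancestors."""
    edges = []
    for lineno, fields in _rows(dag_path):
        if len(fields) < 3:
            raise ParseError(dag_path, lineno, "DAG row needs child, parent, namespace")
        edges.append((fields[0].strip(), fields[1].strip(), fields[2].strip()))
    gene_terms = []
    for lineno, fields in _rows(gaf_path):
        if len(fields) < 2:
            raise ParseError(gaf_path, lineno, "annotation row needs gene, term")
        gene_terms.append((fields[0].strip(), fields[1].strip()))
    return AnnotationCorpus.build(gene_terms, edges)


SCORED_HEADER = ["a", "b", "p_prev", "p_new", "p_final", "star", "sources"]


def write_scored_table(path: PathLike, interactions: Iterable[ScoredInteraction]) -> None:
    """Write scored interactions, sorted by descending score then key."""
    rows = sorted(interactions, key=lambda si: (-si.p_final, si.key))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SCORED_HEADER) + "\n")
        for si in rows:
            fh.write(
                f"{si.key.a}\t{si.key.b}\t{si.p_prev:.12g}\t{si.p_new:.12g}"
                f"\t{si.p_final:.12g}\t{si.star}\t{';'.join(sorted(si.sources))}\n"
            )


def read_scored_table(path: PathLike) -> list[ScoredInteraction]:
    """Read back a table written by :func:`write_scored_table`."""
    out = []
    for lineno, fields in _rows(path):
        if fields[:2] == ["a", "b"]:
            continue  # header
        if len(fields) != 7:
            raise ParseError(path, lineno, "scored row needs 7 columns")
        out.append(
            ScoredInteraction(
                key=canonical_pair(fields[0], fields[1]),
                p_prev=float(fields[2]),
                p_new=float(fields[3]),
                p_final=float(fields[4]),
                star=int(fields[5]),
                sources=frozenset(s for s in fields[6].split(";") if s),
            )
        )
    return out


def write_pair_list(path: PathLike, pairs: Iterable[InteractionKey]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(pairs):
            fh.write(f"{key.a}\t{key.b}\n")


def read_reliability(path: PathLike) -> ReliabilityConfig:
    """Read a ``platform = value`` (or JSON) reliability configuration."""
    text = open(path, encoding="utf-8").read()
    stripped = text.lstrip()
    values: dict[str, float] = {}
    fallback: Optional[float] = None
    if stripped.startswith("{"):
        import json

        data = json.loads(text)
        fallback = data.pop("__fallback__", None)
        values = {str(k): float(v) for k, v in data.items()}
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ParseError(path, lineno, "expected 'platform = value'")
            k, _, v = line.partition("=")
            if k.strip() == "__fallback__":
                fallback = float(v)
            else:
                values[k.strip()] = float(v)
    if fallback is None:
        return ReliabilityConfig(values=values)
    return ReliabilityConfig(values=values, fallback=float(fallback))
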