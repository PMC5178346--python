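"""TSV tables, Graphviz DOT graphs, and intermediary outputs.

The sequence-term matrix is serialized with sequences as columns and
term rows (term id plus human-readable name); the sample-term matrix
with samples as columns.  Each weighted term set also yields a DOT
graph of the ontology hierarchy above it: node fill colors run from
gray at the lowest recorded weight through yellow to orange at the
highest, ancestor-only nodes are unfilled, and node/edge order is
sorted so output is deterministic.  PDF rendering is delegated to
external Graphviz; only DOT text is emitted here.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import UnknownTermError
from .ontology import OntologyGraph
from .search import Hit
from .termspace import TermEvidence

# color ramp endpoints (hex RGB): min -> gray, mid -> yellow, max -> orange
COLOR_MIN = "#c8c8c8"
COLOR_MID = "#ffe800"
COLOR_MAX = "#ff8c00"

FLOAT_FORMAT = "%.6g"  # 6 significant digits: compact and round-trip safe


def _fmt(x: float) -> str:
    return FLOAT_FORMAT % x


def write_seq_term_tsv(
    S: pd.DataFrame,
    graph: OntologyGraph,
    path,
    name_map: Mapping[str, str] | None = None,
) -> None:
    """Write **S** transposed: columns = input sequences, rows = terms.

    Sequence placeholder ids are restored to their original names via
    ``name_map``.  The first two columns carry the term id and its
    human-readable name.
    """
    _write_term_table(S, graph, path, name_map)


def write_sample_term_tsv(N: pd.DataFrame, graph: OntologyGraph, path) -> None:
    """Write **N** transposed: columns = samples, rows = terms."""
    if N.shape[1] == 0:
        import warnings

        warnings.warn(f"{path}: no terms to write; emitting header only", stacklevel=2)
    _write_term_table(N, graph, path, None)


def _write_term_table(matrix, graph, path, name_map) -> None:
    labels = [name_map.get(c, c) if name_map else c for c in matrix.index]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("term_id\tterm_name\t" + "\t".join(map(str, labels)) + "\n")
        for term_id in matrix.columns:
            row = matrix[term_id]
            cells = "\t".join("0" if v == 0 else _fmt(v) for v in row)
            fh.write(f"{term_id}\t{graph.name_of(term_id)}\t{cells}\n")


def read_term_table(path) -> pd.DataFrame:
    """Read a table written by the writers back into its in-memory layout."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df = df.drop(columns=["term_name"]).T
    df.columns.name = "term"
    return df


def _lerp_color(a: str, b: str, t: float) -> tuple[int, int, int]:
    av = [int(a[i : i + 2], 16) for i in (1, 3, 5)]
    bv = [int(b[i : i + 2], 16) for i in (1, 3, 5)]
    return tuple(round(x + (y - x) * t) for x, y in zip(av, bv))


def weight_color(weight: float, lo: float, hi: float) -> str:
    """Hex fill color for a weight on the gray -> yellow -> orange ramp.

    The minimum recorded weight maps to gray; if all weights are equal
    everything is gray.
    """
    if hi <= lo:
        return COLOR_MIN
    t = (weight - lo) / (hi - lo)
    if t <= 0.5:
        rgb = _lerp_color(COLOR_MIN, COLOR_MID, t * 2)
    else:
        rgb = _lerp_color(COLOR_MID, COLOR_MAX, (t - 0.5) * 2)
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def render_dot(
    term_weights: Mapping[str, float], graph: OntologyGraph, label: str = ""
) -> str:
    """Render weighted terms and their ancestor hierarchy as DOT text.

    Nodes are the weighted terms plus all their ancestors, so the drawn
    hierarchy is connected upward; edges follow is_a.  Ancestor-only
    nodes (weight zero) are drawn unfilled.  Output is deterministic:
    nodes and edges are emitted in sorted order.
    """
    for term_id in term_weights:
        if term_id not in graph:
            raise UnknownTermError(f"term {term_id!r} not in ontology")
    nodes: set[str] = set(term_weights)
    for term_id in term_weights:
        nodes |= graph.ancestors(term_id)
    weights = {t: w for t, w in term_weights.items() if w > 0}
    lo = min(weights.values(), default=0.0)
    hi = max(weights.values(), default=0.0)

    lines = ["digraph ontology {"]
    if label:
        lines.append(f'    label="{_dot_escape(label)}";')
    lines.append("    rankdir=BT;")
    lines.append('    node [shape=box, style=rounded, fontname="Helvetica"];')
    for term_id in sorted(nodes):
        attrs = [f'label="{_dot_escape(graph.name_of(term_id))}"']
        w = weights.get(term_id)
        if w is not None:
            attrs.append('style="rounded,filled"')
            attrs.append(f'fillcolor="{weight_color(w, lo, hi)}"')
            attrs.append(f'tooltip="{_fmt(w)}"')
        lines.append(f'    "{_dot_escape(term_id)}" [{", ".join(attrs)}];')
    for child in sorted(nodes):
        if child not in graph:
            continue
        for parent in sorted(graph.graph.successors(child)):
            if parent in nodes:
                lines.append(f'    "{_dot_escape(child)}" -> "{_dot_escape(parent)}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def write_intermediates(
    hit_table: Mapping[str, list[str]],
    evidence: Iterable[TermEvidence],
    graph: OntologyGraph,
    out_dir,
    sequence_order: Iterable[str] = (),
) -> tuple[Path, Path]:
    """Write the filtered hit table and the per-sequence term list.

    The term list has one row per (sequence, term) with the raw tag
    count and the record ids the term was mined from; sequences with no
    terms appear once with a ``-`` marker.
    """
    out_dir = Path(out_dir)
    hits_path = out_dir / "filtered_hits.tsv"
    terms_path = out_dir / "sequence_terms.tsv"

    with open(hits_path, "w", encoding="utf-8") as fh:
        fh.write("sequence\trank\tsubject_id\n")
        for query in sorted(hit_table, key=_placeholder_key):
            for rank, subject in enumerate(hit_table[query], start=1):
                fh.write(f"{query}\t{rank}\t{subject}\n")

    per_seq: dict[str, dict[str, tuple[int, list[str]]]] = {}
    for ev in evidence:
        terms = per_seq.setdefault(ev.query_id, {})
        for term_id, c in ev.term_counts.items():
            count, sources = terms.get(term_id, (0, []))
            terms[term_id] = (count + c, sources + [ev.record_id])
    all_seqs = list(sequence_order) or sorted(per_seq, key=_placeholder_key)
    with open(terms_path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tterm_id\tterm_name\traw_count\tsource_records\n")
        for seq in all_seqs:
            terms = per_seq.get(seq, {})
            if not terms:
                fh.write(f"{seq}\t-\t-\t0\t-\n")
                continue
            for term_id in sorted(terms):
                count, sources = terms[term_id]
                fh.write(
                    f"{seq}\t{term_id}\t{graph.name_of(term_id)}\t{count}\t"
                    + ",".join(sources)
                    + "\n"
                )
    return hits_path, terms_path


def _placeholder_key(qid: str):
    # numeric sort for "C1", "C2", ... ids; lexicographic otherwise
    if len(qid) > 1 and qid[0] == "C" and qid[1:].isdigit():
        return (0, int(qid[1:]), "")
    return (1, 0, qid)
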