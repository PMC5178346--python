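"""Sequence-term and sample-term matrices.

Each input sequence *j* is described by a vector of ontology term
weights :math:`s_{j,k}` — the sequence-term matrix **S** — built from
the term counts tagged in the isolation sources of its database
homologs.  Raw counts :math:`s'_{j,k}` accumulate under one of three
strategies:

``flat``
    raw occurrence counts over all evidence rows (the default);
``unique_isolation``
    identical isolation-source texts count once per input sequence;
``unique_pubmed_unique_isolation``
    evidence rows sharing both the isolation-source text and the PubMed
    id (the same study) count once per input sequence.

Rows are then normalized to sum to 1.0:
:math:`s_{j,k} = s'_{j,k} / \\sum_l s'_{j,l}`; a sequence whose homologs
carried no environmental information keeps an all-zero row and is
reported separately.

With a frequency matrix **F** (:math:`f_{i,j}`, sample *i* x sequence
*j*) the sample-term matrix **N** is the abundance-weighted sum
:math:`n'_{i,k} = \\sum_j f_{i,j} s_{j,k}`, row-normalized the same way.

Optional transforms run in the order accumulate -> backtrack ->
restrict -> normalize, so ancestor terms inside a restricted subtree
still receive propagated weight and rows stay interpretable as
compositions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError, UnknownTermError
from .ontology import OntologyGraph

STRATEGIES = ("flat", "unique_isolation", "unique_pubmed_unique_isolation")


@dataclass
class TermEvidence:
    """Term counts tagged in one homolog's isolation source for one query."""

    query_id: str
    record_id: str
    isolation_source: str
    pubmed_id: str | None = None
    term_counts: dict[str, int] = field(default_factory=dict)


def accumulate_counts(
    evidence: Iterable[TermEvidence], strategy: str = "flat"
) -> dict[str, dict[str, int]]:
    """Accumulate per-query raw term counts ``s'`` under a strategy.

    Deduplication keys (applied within each query, keeping the first
    evidence row): none for ``flat``; the whitespace-trimmed isolation
    source for ``unique_isolation``; the (isolation source, pubmed id)
    pair for ``unique_pubmed_unique_isolation``, a missing pubmed id
    participating as an explicit absent marker.
    """
    if strategy not in STRATEGIES:
        raise InputError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    counts: dict[str, dict[str, int]] = {}
    seen: dict[str, set] = {}
    for ev in evidence:
        text = ev.isolation_source.strip()
        if strategy == "unique_isolation":
            key = text
        elif strategy == "unique_pubmed_unique_isolation":
            key = (text, ev.pubmed_id)
        else:
            key = None
        if key is not None:
            done = seen.setdefault(ev.query_id, set())
            if key in done:
                continue
            done.add(key)
        acc = counts.setdefault(ev.query_id, {})
        for term_id, n in ev.term_counts.items():
            acc[term_id] = acc.get(term_id, 0) + n
    return counts


def backtrack(counts: dict[str, int], graph: OntologyGraph) -> dict[str, int]:
    """Propagate each term's count up the ontology graph.

    Every ancestor of a counted term receives that count exactly once,
    regardless of how many is_a paths reach it; original counts are
    retained.  Counts never decrease.
    """
    out = dict(counts)
    for term_id, c in counts.items():
        if term_id not in graph:
            raise UnknownTermError(f"counted term {term_id!r} not in ontology")
        for anc in graph.ancestors(term_id):
            out[anc] = out.get(anc, 0) + c
    return out


def apply_restriction(
    counts: dict[str, int], graph: OntologyGraph, root: str
) -> dict[str, int]:
    """Keep only counts for terms at or below ``root``; values untouched."""
    allowed = graph.restrict_to(root, counts.keys())
    return {t: c for t, c in counts.items() if t in allowed}


def normalize_rows(
    raw: dict[str, dict[str, int]],
    sequence_order: Sequence[str],
    term_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the sequence-term matrix **S** with rows normalized to 1.0.

    Rows follow ``sequence_order``; columns default to lexicographic term
    order for reproducible output.  All-zero rows (sequences without
    environmental information) are preserved as zero; list them with
    :func:`unannotated_rows`.
    """
    if term_order is None:
        term_order = sorted({t for c in raw.values() for t in c})
    S = pd.DataFrame(0.0, index=list(sequence_order), columns=list(term_order))
    S.index.name = "sequence"
    S.columns.name = "term"
    for qid, counts in raw.items():
        if qid not in S.index:
            continue
        for term_id, c in counts.items():
            if c < 0:
                raise InputError(f"negative count for {qid}/{term_id}")
            S.loc[qid, term_id] = float(c)
    sums = S.sum(axis=1)
    nonzero = sums > 0
    S.loc[nonzero] = S.loc[nonzero].div(sums[nonzero], axis=0)
    return S


def unannotated_rows(matrix: pd.DataFrame) -> list[str]:
    """Row labels whose weights are entirely zero (no environmental info)."""
    return list(matrix.index[matrix.sum(axis=1) == 0])


def sample_matrix(freq: pd.DataFrame, S: pd.DataFrame) -> pd.DataFrame:
    """Sample-term matrix **N**: abundance-weighted term vectors per sample.

    ``freq`` is samples x sequences, ``S`` sequences x terms; their
    sequence sets must agree.  Computes :math:`n'_{i,k} = \\sum_j f_{i,j}
    s_{j,k}` and normalizes each nonzero row by its total.
    """
    freq_seqs, s_seqs = set(freq.columns), set(S.index)
    if freq_seqs != s_seqs:
        missing = sorted(freq_seqs ^ s_seqs)
        raise InputError(
            "frequency matrix and sequence-term matrix disagree on "
            f"sequences: {', '.join(missing)}"
        )
    N = freq[list(S.index)].to_numpy() @ S.to_numpy()
    N = pd.DataFrame(N, index=freq.index, columns=S.columns)
    N.index.name = "sample"
    N.columns.name = "term"
    sums = N.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(
            "samples with no term weight kept as zero rows: "
            + ", ".join(map(str, N.index[zero])),
            stacklevel=2,
        )
    N.loc[~zero] = N.loc[~zero].div(sums[~zero], axis=0)
    return N
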