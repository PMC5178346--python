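"""Single-run orchestration of the full annotation pipeline.

Stages run in a fixed order: rename -> optional abundance filter ->
similarity search (or ingest a results file) -> hit filtering ->
metadata lookup -> tagging -> count accumulation -> optional
backtracking -> optional restriction -> row normalization -> optional
sample matrix -> outputs.  A run manifest records every parameter and
input checksum; the search stage — the only expensive one — is skipped
on rerun when the manifest matches and its output is present.  The
pipeline contains no randomness: identical inputs give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import metadata_store, reporting, search, sequence_io, tagger, termspace
from .errors import EnvotagError, InputError
from .ontology import OntologyGraph, parse_obo
from .search import FilterParams
from .termspace import TermEvidence

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


@dataclass
class PipelineConfig:
    """Resolved options for one pipeline run; defaults echo the tool's defaults."""

    fasta: str
    out_dir: str
    obo: str
    store: str
    abundances: str | None = None
    search_results: str | None = None
    db: str | None = None
    stoplist: str | None = None
    top_n: int | None = None  # default: use all sequences
    filters: FilterParams = field(default_factory=FilterParams)
    strategy: str = "flat"
    backtracking: bool = False
    restrict: str | None = None
    threads: int = 1
    transpose: bool = False
    ignore_missing: bool = False


@dataclass
class PipelineResult:
    """In-memory handles to the run's main artifacts."""

    out_dir: Path
    seq_term_matrix: object  # pandas DataFrame, sequences x terms
    sample_term_matrix: object | None
    hit_table: dict
    evidence: list
    unannotated: list
    name_map: dict


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig, runner=None) -> PipelineResult:
    """Execute the pipeline; returns matrices and writes all outputs.

    ``runner`` overrides the external-aligner invocation (see
    :mod:`envotag.search`); it is ignored when ``search_results`` is given.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    _stage("parse and rename FASTA")
    seqs, name_map = sequence_io.parse_and_rename(config.fasta)
    sequence_io.write_name_map(name_map, out_dir / "name_map.tsv")
    all_seqs = seqs  # pre-filter list; ingested results may cover dropped queries

    freq = None
    if config.abundances:
        _stage("read frequency matrix")
        raw_freq = sequence_io.read_frequency_matrix(
            config.abundances, transpose=config.transpose
        )
        freq = sequence_io.map_frequency_to_placeholders(
            raw_freq, name_map, ignore_missing=config.ignore_missing
        )
        if config.top_n is not None:
            _stage(f"filter to top {config.top_n} sequences by total abundance")
            seqs = sequence_io.filter_top_n(seqs, freq, config.top_n)
            freq = freq[[r.new_id for r in seqs]]
    elif config.top_n is not None:
        logger.warning("no frequency matrix given; abundance filtering skipped")

    _stage("load ontology and build lexicon")
    graph = parse_obo(config.obo)
    stop = tagger.load_stoplist(config.stoplist)
    lexicon = tagger.build_lexicon(graph, stop)

    manifest = _write_manifest(config, out_dir)

    # accept results keyed by placeholder or original ids
    query_lengths = {r.new_id: len(r.sequence) for r in all_seqs}
    query_lengths.update({r.original_id: len(r.sequence) for r in all_seqs})
    to_placeholder = {r.original_id: r.new_id for r in all_seqs}
    if config.search_results:
        _stage("ingest similarity-search results")
        results_path = Path(config.search_results)
    else:
        _stage("similarity search")
        results_path = out_dir / "search_results.tsv"
        if _search_cached(out_dir, manifest, results_path):
            logger.info("search results unchanged since last run; reusing")
        else:
            if runner is None and not config.db:
                raise InputError("either --db or --search-results is required")
            search.run_search(
                seqs, config.db or "", results_path, threads=config.threads, runner=runner
            )
    hits = search.parse_tabular(results_path, query_lengths)
    for hit in hits:
        hit.query_id = to_placeholder.get(hit.query_id, hit.query_id)

    _stage("filter hits")
    hit_table = search.filter_hits(hits, config.filters)
    kept = {r.new_id for r in seqs}
    hit_table = {q: subs for q, subs in hit_table.items() if q in kept}

    _stage("look up isolation sources")
    record_ids = sorted(
        {search.extract_record_id(s) for subs in hit_table.values() for s in subs}
    )
    with metadata_store.open_store(config.store) as store:
        annotations = store.lookup_many(record_ids)

    _stage("tag isolation sources")
    evidence: list[TermEvidence] = []
    for rec in seqs:
        for subject in hit_table.get(rec.new_id, []):
            rid = search.extract_record_id(subject)
            ann = annotations.get(rid)
            if ann is None:
                continue
            hits_for_text = tagger.tag_text(lexicon, ann.isolation_source)
            evidence.append(
                TermEvidence(
                    query_id=rec.new_id,
                    record_id=rid,
                    isolation_source=ann.isolation_source,
                    pubmed_id=ann.pubmed_id,
                    term_counts=tagger.count_terms(hits_for_text),
                )
            )

    _stage(f"accumulate counts ({config.strategy})")
    raw_counts = termspace.accumulate_counts(evidence, config.strategy)
    if config.backtracking:
        _stage("backtrack counts up the ontology")
        raw_counts = {q: termspace.backtrack(c, graph) for q, c in raw_counts.items()}
    if config.restrict:
        _stage(f"restrict to descendants of {config.restrict}")
        raw_counts = {
            q: termspace.apply_restriction(c, graph, config.restrict)
            for q, c in raw_counts.items()
        }

    _stage("normalize sequence-term matrix")
    S = termspace.normalize_rows(raw_counts, [r.new_id for r in seqs])
    unannotated = termspace.unannotated_rows(S)
    if unannotated:
        originals = [name_map[q] for q in unannotated]
        logger.info(
            "%d sequence(s) matched no environmental information: %s",
            len(originals), ", ".join(originals),
        )
        (out_dir / "unannotated_sequences.txt").write_text(
            "\n".join(originals) + "\n", "utf-8"
        )

    N = None
    if freq is not None:
        _stage("compute sample-term matrix")
        N = termspace.sample_matrix(freq, S)

    _stage("write outputs")
    reporting.write_seq_term_tsv(S, graph, out_dir / "seq_term_matrix.tsv", name_map)
    if N is not None:
        reporting.write_sample_term_tsv(N, graph, out_dir / "sample_term_matrix.tsv")
    reporting.write_intermediates(
        hit_table, evidence, graph, out_dir, sequence_order=[r.new_id for r in seqs]
    )
    dot_dir = out_dir / "graphs"
    dot_dir.mkdir(exist_ok=True)
    for rec in seqs:
        weights = {t: w for t, w in S.loc[rec.new_id].items() if w > 0}
        if weights:
            dot = reporting.render_dot(weights, graph, label=name_map[rec.new_id])
            (dot_dir / f"{rec.new_id}.dot").write_text(dot, "utf-8")
    if N is not None:
        for sample in N.index:
            weights = {t: w for t, w in N.loc[sample].items() if w > 0}
            if weights:
                dot = reporting.render_dot(weights, graph, label=str(sample))
                (dot_dir / f"sample_{sample}.dot").write_text(dot, "utf-8")

    return PipelineResult(
        out_dir=out_dir,
        seq_term_matrix=S,
        sample_term_matrix=N,
        hit_table=hit_table,
        evidence=evidence,
        unannotated=unannotated,
        name_map=name_map,
    )


def _manifest_payload(config: PipelineConfig) -> dict:
    payload = asdict(config)
    payload["filters"] = asdict(config.filters)
    payload["input_checksums"] = {}
    for key in ("fasta", "abundances", "search_results", "obo", "store", "stoplist"):
        path = getattr(config, key)
        if path and Path(path).exists():
            payload["input_checksums"][key] = _sha256(path)
    return payload


def _write_manifest(config: PipelineConfig, out_dir: Path) -> dict:
    payload = _manifest_payload(config)
    previous = None
    manifest_path = out_dir / MANIFEST_NAME
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text("utf-8"))
        except json.JSONDecodeError:
            previous = None
    payload["_previous_matches"] = previous is not None and {
        k: v for k, v in previous.items() if not k.startswith("_")
    } == {k: v for k, v in payload.items() if not k.startswith("_")}
    manifest_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", "utf-8")
    return payload


def _search_cached(out_dir: Path, manifest: dict, results_path: Path) -> bool:
    return bool(manifest.get("_previous_matches")) and results_path.exists()


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "EnvotagError",
]
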