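"""Nucleotide similarity search and species-level hit filtering.

The search itself is delegated to an external aligner (BLAST against
NCBI "nt" in typical use) behind a thin contract: any tool that emits
the standard 12-column tabular output (``qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore``) works, and
a results file produced elsewhere can be ingested directly.

Hits are filtered to approximate species-level homologs: e-value,
query coverage (alignment length / query length) and identity
thresholds, then at most ``max_targets`` hits per query.  Defaults are
e-value 1e-4, coverage 0.97, identity 0.97, 10 targets.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from .errors import InputError, MissingDependencyError, ParseError, SearchError
from .sequence_io import RenamedSequence, write_renamed_fasta

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

# runner contract: (chunk_fasta_path, db, out_path) -> writes tabular hits
SearchRunner = Callable[[Path, str, Path], None]


@dataclass
class Hit:
    """One row of tabular similarity-search output, joined with query length."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ParseError(
                f"hit {self.query_id}/{self.subject_id}: "
                f"percent identity {self.pct_identity} outside [0, 100]"
            )
        if self.aln_length < 1:
            raise ParseError(
                f"hit {self.query_id}/{self.subject_id}: alignment length < 1"
            )
        if self.evalue < 0:
            raise ParseError(
                f"hit {self.query_id}/{self.subject_id}: negative e-value"
            )


@dataclass
class FilterParams:
    """Hit-filtering thresholds; defaults approximate species boundaries."""

    max_evalue: float = 1e-4
    min_coverage: float = 0.97
    min_identity: float = 0.97
    max_targets: int = 10


def _blast_runner(chunk: Path, db: str, out: Path) -> None:
    exe = shutil.which("blastn")
    if exe is None:
        raise MissingDependencyError(
            "blastn not found on PATH; install BLAST+ or pass --search-results"
        )
    cmd = [exe, "-query", str(chunk), "-db", db, "-outfmt", "6", "-out", str(out)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise SearchError(f"blastn exited {proc.returncode}: {proc.stderr.strip()}")


def run_search(
    seqs: Sequence[RenamedSequence],
    db: str,
    out_path,
    threads: int = 1,
    runner: SearchRunner | None = None,
) -> Path:
    """Run the similarity search, chunking the input across ``threads``.

    With ``threads > 1`` the FASTA is split into roughly equal chunks,
    each searched independently, and the tabular outputs concatenated in
    chunk order.  ``runner`` defaults to invoking ``blastn``; any callable
    honouring the (chunk, db, out) contract may replace it, which is how
    tests use a stub aligner over packaged fixtures.
    """
    if not seqs:
        raise InputError("no sequences to search")
    if threads < 1:
        raise InputError(f"threads must be >= 1, got {threads}")
    runner = runner or _blast_runner
    out_path = Path(out_path)
    n_chunks = min(threads, len(seqs))
    size, rem = divmod(len(seqs), n_chunks)
    chunks: list[list[RenamedSequence]] = []
    pos = 0
    for i in range(n_chunks):
        step = size + (1 if i < rem else 0)
        chunks.append(list(seqs[pos : pos + step]))
        pos += step

    with tempfile.TemporaryDirectory(prefix="envotag_search_") as tmp:
        tmpdir = Path(tmp)
        part_paths = []
        for i, chunk in enumerate(chunks):
            chunk_fasta = tmpdir / f"chunk_{i}.fasta"
            part = tmpdir / f"chunk_{i}.tsv"
            write_renamed_fasta(chunk, chunk_fasta)
            runner(chunk_fasta, db, part)
            part_paths.append(part)
        with open(out_path, "w", encoding="utf-8") as out:
            for part in part_paths:
                out.write(part.read_text(encoding="utf-8"))
    return out_path


def parse_tabular(path, query_lengths: dict[str, int]) -> list[Hit]:
    """Parse 12-column tabular alignment output into :class:`Hit` records.

    ``query_lengths`` (from the FASTA) is joined onto each row.  Raises
    :class:`ParseError` with the line number on a wrong column count and
    :class:`InputError` when a query id has no known length.
    """
    hits: list[Hit] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {line_no}: expected >=12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            qseqid, sseqid = fields[0], fields[1]
            if qseqid not in query_lengths:
                raise InputError(
                    f"{path}: line {line_no}: query {qseqid!r} has no known length"
                )
            try:
                hit = Hit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    query_length=query_lengths[qseqid],
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {line_no}: {exc}") from exc
            hits.append(hit)
    return hits


def filter_hits(hits: Sequence[Hit], params: FilterParams | None = None) -> dict[str, list[str]]:
    """Select the best hits per query and return the hit table.

    A hit survives when e-value <= ``max_evalue`` AND coverage
    (aln_length / query_length) >= ``min_coverage`` AND identity
    (pct_identity / 100) >= ``min_identity``.  Survivors are ranked by
    ascending e-value, ties by descending bitscore then subject id, and
    truncated to ``max_targets``; duplicate subjects collapse to their
    best-ranked occurrence.  Queries may map to zero, one or more
    subject record ids.
    """
    params = params or FilterParams()
    by_query: dict[str, list[Hit]] = {}
    for hit in hits:
        coverage = hit.aln_length / hit.query_length
        if (
            hit.evalue <= params.max_evalue
            and coverage >= params.min_coverage
            and hit.pct_identity / 100.0 >= params.min_identity
        ):
            by_query.setdefault(hit.query_id, []).append(hit)

    table: dict[str, list[str]] = {}
    for query, group in by_query.items():
        group.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
        retained: list[str] = []
        for hit in group:
            if hit.subject_id not in retained:
                retained.append(hit.subject_id)
            if len(retained) == params.max_targets:
                break
        table[query] = retained
    return table


def extract_record_id(subject_id: str) -> str:
    """Pull the database record identifier out of a subject id string.

    The legacy ``gi|<digits>|...`` dialect yields the GI digits; anything
    else passes through verbatim (accession.version kept intact).
    """
    if not subject_id:
        raise InputError("empty subject id")
    parts = subject_id.split("|")
    if len(parts) >= 2 and parts[0] == "gi" and parts[1].isdigit():
        return parts[1]
    return subject_id
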