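"""FASTA intake, placeholder renaming, and frequency-matrix handling.

Input sequence names are replaced by placeholder ids "C1", "C2", ... in
file order before anything else runs, so downstream stages never see odd
encodings or ambiguous characters; the bijective name map is kept so all
outputs can be re-labeled with the original ids.

The frequency (count) matrix is a tab-delimited table of per-sample
sequence counts — typically an OTU table with rows = sequences and
columns = samples.  Internally it is held samples x sequences
(:math:`f_{i,j}` for sample *i*, sequence *j*).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .errors import InputError, ParseError


@dataclass
class RenamedSequence:
    """A FASTA record under its placeholder name."""

    new_id: str
    original_id: str
    sequence: str


def parse_and_rename(path) -> tuple[list[RenamedSequence], dict[str, str]]:
    """Read a FASTA file and rename records to "C1", "C2", ... in file order.

    Original ids are the headers truncated at the first whitespace.  Returns
    the renamed records and the new_id -> original_id map.

    Raises
    ------
    InputError
        If the file holds no records or original headers are duplicated.
    """
    records = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        original = rec.id  # header truncated at first whitespace
        seen[original] = seen.get(original, 0) + 1
        records.append(RenamedSequence(f"C{i}", original, str(rec.seq)))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    dupes = sorted(h for h, n in seen.items() if n > 1)
    if dupes:
        raise InputError(f"duplicate FASTA headers: {', '.join(dupes)}")
    name_map = {r.new_id: r.original_id for r in records}
    return records, name_map


def write_renamed_fasta(seqs: list[RenamedSequence], path) -> None:
    """Write records under their placeholder names (one line per sequence)."""
    with open(path, "w", encoding="ascii") as fh:
        for rec in seqs:
            fh.write(f">{rec.new_id}\n{rec.sequence}\n")


def write_name_map(name_map: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("new_id\toriginal_id\n")
        for new_id, original in name_map.items():
            fh.write(f"{new_id}\t{original}\n")


def read_frequency_matrix(path, transpose: bool = False) -> pd.DataFrame:
    """Read the tab-delimited count matrix into a samples x sequences frame.

    The file is expected with rows = sequences and columns = samples (the
    usual OTU-table orientation); pass ``transpose=True`` for the opposite
    layout.  The returned frame is indexed by sample name with sequence ids
    as columns and holds non-negative numbers.

    Raises
    ------
    ParseError
        On non-numeric cells (named by row and column) or ragged rows.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: ragged or malformed table: {exc}") from exc
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = numeric.isna().stack()
        row, col = bad[bad].index[0]
        raise ParseError(
            f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
            f"{df.loc[row, col]!r}"
        )
    if (numeric < 0).any().any():
        raise ParseError(f"{path}: negative counts are not allowed")
    freq = numeric if transpose else numeric.T
    freq.index.name = "sample"
    freq.columns.name = "sequence"
    if (freq.to_numpy() == 0).all():
        warnings.warn(f"{path}: frequency matrix is entirely zero", stacklevel=2)
    return freq


def map_frequency_to_placeholders(
    freq: pd.DataFrame,
    name_map: dict[str, str],
    ignore_missing: bool = False,
) -> pd.DataFrame:
    """Relabel frequency-matrix sequence columns with placeholder ids.

    Every FASTA sequence must appear in the matrix; with ``ignore_missing``
    absent sequences get a zero column and a warning instead of an error.
    Extra matrix columns not present in the FASTA are dropped.
    """
    reverse = {orig: new for new, orig in name_map.items()}
    missing = [orig for orig in reverse if orig not in freq.columns]
    if missing and not ignore_missing:
        raise InputError(
            "sequences absent from the frequency matrix: " + ", ".join(sorted(missing))
        )
    if missing:
        warnings.warn(
            f"{len(missing)} sequence(s) absent from the frequency matrix; "
            "treated as zero abundance",
            stacklevel=2,
        )
    out = pd.DataFrame(
        0.0, index=freq.index, columns=[new for new in name_map], dtype=float
    )
    for new_id, orig in name_map.items():
        if orig in freq.columns:
            out[new_id] = freq[orig].astype(float)
    out.index.name = "sample"
    out.columns.name = "sequence"
    return out


def filter_top_n(
    seqs: list[RenamedSequence], freq: pd.DataFrame, n: int
) -> list[RenamedSequence]:
    """Keep the ``n`` sequences with the highest total count across samples.

    Ties are broken by input-file order (earlier wins); output preserves
    input order.  ``n`` at or above the number of sequences keeps all.
    """
    if n <= 0:
        raise InputError(f"top-n must be positive, got {n}")
    totals = freq.sum(axis=0)
    order = {rec.new_id: i for i, rec in enumerate(seqs)}
    ranked = sorted(seqs, key=lambda r: (-float(totals.get(r.new_id, 0.0)), order[r.new_id]))
    keep = {r.new_id for r in ranked[:n]}
    return [r for r in seqs if r.new_id in keep]
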