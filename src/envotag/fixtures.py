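"""Self-contained synthetic inputs exercising every pipeline branch.

Nothing here is downloaded: the generator writes a miniature ontology,
random nucleotide sequences, a frequency matrix, a tabular hit file and
a metadata-store TSV whose isolation sources are drawn from templates
built on the mini-ontology's surface forms.  Sequences are assigned
rotating *roles* so the dataset covers the interesting branches:
threshold failures of each kind, a query overflowing the per-query
target cap, store misses, duplicate texts and shared PubMed ids (which
discriminate the three accumulation strategies), and sequences that end
up with no environmental information at all.

Because every hit and store row is constructed deliberately, the
generator can tabulate the expected raw term counts per query and
strategy by simple set logic over its own templates — an oracle
independent of the tagging and accumulation code — and packages them in
a machine-readable expectation file next to the data.

All randomness is seeded and confined to this module; the pipeline
itself is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InputError

MINI_OBO = """\
format-version: 1.2
ontology: mini-envo-fixture

[Term]
id: E:1
name: environmental material

[Term]
id: E:2
name: water
is_a: E:1 ! environmental material

[Term]
id: E:3
name: fresh water
is_a: E:2 ! water

[Term]
id: E:4
name: sea water
is_a: E:2 ! water

[Term]
id: E:5
name: soil
is_a: E:1 ! environmental material
"""

DIAMOND_OBO = MINI_OBO + """
[Term]
id: D:W
name: diamond sink

[Term]
id: D:Y
name: diamond left
is_a: D:W

[Term]
id: D:Z
name: diamond right
is_a: D:W

[Term]
id: D:X
name: diamond source
is_a: D:Y
is_a: D:Z
"""

# isolation-source templates and the term counts the mini-ontology
# lexicon yields on them (tabulated by hand; the tests' oracle)
TEMPLATES: dict[str, dict[str, int]] = {
    "fresh water from lake": {"E:3": 1},
    "agricultural soil": {"E:5": 1},
    "surface sea water": {"E:4": 1},
    "water and soil mixture": {"E:2": 1, "E:5": 1},
    "deep subsurface sample": {},
    "environmental material from soil": {"E:1": 1, "E:5": 1},
}
_T1, _T2, _T3, _T4, _T5, _T6 = TEMPLATES  # template names in order

# hit parameter presets: (pident, aln_length, evalue) for query length 120
_PASS = (98.5, 120, 1e-20)
_FAIL_EVALUE = (98.5, 120, 1e-2)
_FAIL_COVERAGE = (98.5, 100, 1e-20)
_FAIL_IDENTITY = (95.0, 120, 1e-20)

SEQ_LENGTH = 120


def make_mini_ontology(out_path, diamond: bool = False) -> Path:
    """Write the 5-term fixture ontology (or its diamond-DAG variant)."""
    out_path = Path(out_path)
    out_path.write_text(DIAMOND_OBO if diamond else MINI_OBO, encoding="utf-8")
    return out_path


@dataclass
class ToyDataset:
    """Paths of one generated toy dataset plus its expectation file."""

    fasta: Path
    abundances: Path
    hits: Path
    store_tsv: Path
    obo: Path
    expected_counts: Path


def _role_records(role: int, pm: list[str]) -> list[tuple[str, str | None, tuple]]:
    """Evidence plan for one role: (template, pubmed_id, hit preset) per record.

    Special markers in the template slot: ``None`` entries never reach the
    store ("MISS" subjects); roles may also return an empty plan (no hits).
    """
    if role == 0:  # duplicate text + same pubmed, plus a distinct record
        return [(_T1, pm[0], _PASS), (_T1, pm[0], _PASS), (_T2, None, _PASS)]
    if role == 1:  # same text, distinct pubmed ids (strategies 2 vs 3 differ)
        return [(_T1, pm[1], _PASS), (_T1, pm[2], _PASS)]
    if role == 2:  # one hit failing each filter threshold
        return [(_T1, pm[0], _FAIL_EVALUE), (_T2, None, _FAIL_COVERAGE), (_T3, None, _FAIL_IDENTITY)]
    if role == 3:  # 12 passing hits; only the 10 best e-values are retained
        plan = []
        for k in range(12):
            if k < 5:
                tpl, pub = _T1, pm[3]
            elif k < 8:
                tpl, pub = _T2, [pm[4], pm[5], None][k - 5]
            elif k < 10:
                tpl, pub = _T3, [pm[6], None][k - 8]
            else:  # ranked past max_targets; must not contribute
                tpl, pub = _T4, pm[7]
            plan.append((tpl, pub, (98.5, 120, 1e-30 * 10.0**k)))
        return plan
    if role == 4:  # passing hits whose subjects are absent from the store
        return [(None, None, _PASS), (None, None, _PASS)]
    if role == 5:  # no hits at all
        return []
    if role == 6:  # single record, two terms in one text
        return [(_T4, pm[8], _PASS)]
    if role == 7:  # isolation source with no ontology terms
        return [(_T5, None, _PASS)]
    if role == 8:  # distinct texts; all strategies coincide
        return [(_T6, pm[9], _PASS), (_T3, None, _PASS)]
    # role 9: same text under distinct pubmeds plus a pubmed shared across texts
    return [(_T2, pm[10], _PASS), (_T2, pm[11], _PASS), (_T3, pm[10], _PASS)]


def _expected_for_plan(plan, max_targets: int = 10) -> dict[str, dict[str, int]]:
    """Brute-force expectation: retained records -> counts per strategy."""
    passing = [
        (tpl, pub, preset)
        for tpl, pub, preset in plan
        if preset[2] <= 1e-4 and preset[1] / SEQ_LENGTH >= 0.97 and preset[0] / 100 >= 0.97
    ]
    passing.sort(key=lambda r: r[2][2])  # ascending e-value; construction has no ties
    retained = [(tpl, pub) for tpl, pub, _ in passing[:max_targets] if tpl is not None]

    def tally(rows):
        counts: dict[str, int] = {}
        for tpl, _ in rows:
            for term, c in TEMPLATES[tpl].items():
                counts[term] = counts.get(term, 0) + c
        return counts

    uniq_iso, seen_txt = [], set()
    for tpl, pub in retained:
        if tpl not in seen_txt:
            seen_txt.add(tpl)
            uniq_iso.append((tpl, pub))
    uniq_pair, seen_pair = [], set()
    for tpl, pub in retained:
        if (tpl, pub) not in seen_pair:
            seen_pair.add((tpl, pub))
            uniq_pair.append((tpl, pub))
    return {
        "flat": tally(retained),
        "unique_isolation": tally(uniq_iso),
        "unique_pubmed_unique_isolation": tally(uniq_pair),
    }


def make_toy_dataset(
    n_seqs: int = 10, n_samples: int = 3, seed: int = 1, out_dir: str | Path = "."
) -> ToyDataset:
    """Generate the toy dataset; identical seeds yield identical files."""
    if n_seqs < 1 or n_samples < 1:
        raise InputError("n_seqs and n_samples must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = f"toy_seed{seed}_"
    rng = np.random.default_rng(seed)

    paths = ToyDataset(
        fasta=out_dir / f"{prefix}seqs.fasta",
        abundances=out_dir / f"{prefix}abundances.tsv",
        hits=out_dir / f"{prefix}hits.tsv",
        store_tsv=out_dir / f"{prefix}store.tsv",
        obo=out_dir / f"{prefix}mini.obo",
        expected_counts=out_dir / f"{prefix}expected_counts.json",
    )
    make_mini_ontology(paths.obo)

    # FASTA: random nucleotides under OTU-style headers (one odd header)
    bases = np.array(list("ACGT"))
    with open(paths.fasta, "w", encoding="utf-8") as fh:
        for j in range(n_seqs):
            header = f"OTU_{j + 1};size={j + 2}" if j == 2 else f"OTU_{j + 1}"
            seq = "".join(bases[rng.integers(0, 4, SEQ_LENGTH)])
            fh.write(f">{header}\n{seq}\n")

    # frequency matrix: heavy-tailed counts, rows = sequences
    counts = rng.geometric(0.05, size=(n_seqs, n_samples)) - 1
    with open(paths.abundances, "w", encoding="utf-8") as fh:
        fh.write("otu\t" + "\t".join(f"sample_{i + 1}" for i in range(n_samples)) + "\n")
        for j in range(n_seqs):
            header = f"OTU_{j + 1};size={j + 2}" if j == 2 else f"OTU_{j + 1}"
            fh.write(header + "\t" + "\t".join(map(str, counts[j])) + "\n")

    hit_rows: list[str] = []
    store_rows: list[tuple[str, str, str]] = []
    expected: dict[str, dict[str, dict[str, int]]] = {}
    miss_counter = 0
    for j in range(n_seqs):
        qid = f"C{j + 1}"
        role = j % 10
        pm = [f"PM{j + 1}_{k}" for k in range(12)]
        plan = _role_records(role, pm)
        expected[qid] = _expected_for_plan(plan)
        for k, (tpl, pub, (pident, aln, evalue)) in enumerate(plan):
            rid = str(9000 + 100 * j + k)
            if tpl is None:
                subject = f"MISS{miss_counter}"
                miss_counter += 1
            elif j % 2 == 0:
                subject = f"gi|{rid}|gb|AY{rid}.1|"
                store_rows.append((rid, tpl, pub or ""))
            else:
                subject = f"KX{rid}.1"
                store_rows.append((f"KX{rid}.1", tpl, pub or ""))
            mism = int(round(aln * (1 - pident / 100)))
            hit_rows.append(
                f"{qid}\t{subject}\t{pident}\t{aln}\t{mism}\t0\t1\t{aln}\t1\t{aln}"
                f"\t{evalue:g}\t{200.0 - k:g}"
            )

    paths.hits.write_text("\n".join(hit_rows) + ("\n" if hit_rows else ""), "utf-8")
    with open(paths.store_tsv, "w", encoding="utf-8") as fh:
        fh.write("record_id\tisolation_source\tpubmed_id\n")
        for rid, text, pub in store_rows:
            fh.write(f"{rid}\t{text}\t{pub}\n")
    paths.expected_counts.write_text(
        json.dumps(expected, indent=1, sort_keys=True) + "\n", "utf-8"
    )
    return paths


def stub_runner(hits_path):
    """Search runner over a packaged tabular "database" for tests.

    Returns a callable matching the :mod:`envotag.search` runner contract
    that selects the rows of ``hits_path`` belonging to the queries in the
    chunk FASTA, preserving file order.
    """
    hits_path = Path(hits_path)

    def run(chunk_fasta: Path, db: str, out: Path) -> None:
        queries = {
            line[1:].split()[0]
            for line in Path(chunk_fasta).read_text("utf-8").splitlines()
            if line.startswith(">")
        }
        rows = [
            line
            for line in hits_path.read_text("utf-8").splitlines()
            if line and line.split("\t", 1)[0] in queries
        ]
        Path(out).write_text("\n".join(rows) + ("\n" if rows else ""), "utf-8")

    return run
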