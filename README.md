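# envotag

Environmental-source annotation of DNA sequences. Given a FASTA file of
sequences — typically OTU representatives from an amplicon survey — and
the tabular output of a nucleotide similarity search against a reference
database, `envotag` mines the free-text *isolation source* metadata of
each sequence's close database homologs for terms of the Environment
Ontology (EnvO), and summarizes where each sequence, and each biological
sample, has previously been observed.

It is aimed at microbial ecologists who want to place their community
data in a wider environmental context: source tracking, habitat-breadth
analyses, and ordination of samples in "environment space" rather than
taxon space.

## Model

For each input sequence *j*, species-level homologs are selected from
the search hits (e-value ≤ 10⁻⁴, query coverage ≥ 0.97, identity ≥ 0.97,
at most 10 targets per query, by default). The isolation-source text of
each retained record is tagged with EnvO terms by a dictionary-based
named-entity recognizer (term names and exact synonyms, token-based,
case-insensitive, leftmost-longest, with a stop-list of ambiguous
words). Raw term counts *s′<sub>j,k</sub>* accumulate under one of three
strategies — `flat` (every occurrence counts; the default),
`unique_isolation` (identical isolation-source texts count once per
sequence), `unique_pubmed_unique_isolation` (records sharing both the
text and the PubMed id count once) — and each row is normalized to a
composition:

    s_{j,k} = s'_{j,k} / Σ_l s'_{j,l}

giving the sequence–term matrix **S**. With a frequency matrix **F**
(*f<sub>i,j</sub>*, sample *i* × sequence *j*), the sample–term matrix
**N** is the abundance-weighted sum

    n'_{i,k} = Σ_j f_{i,j} · s_{j,k},    n_{i,k} = n'_{i,k} / Σ_l n'_{i,l}

Two optional transforms act on the raw counts before normalization:
*backtracking* propagates each term's count to all of its ontology
ancestors, and *restriction* keeps only the descendants of one chosen
term (e.g. `ENVO:00010483`, "environmental material").

## Worked example

The package ships a generator for a fully self-contained toy dataset
(10 sequences × 3 samples, a 5-term mini-ontology, a tabular hit file
and a metadata store), so the whole pipeline runs without any database:

```python
import pathlib, tempfile
from envotag.fixtures import make_toy_dataset
from envotag.metadata_store import build_store
from envotag.pipeline import PipelineConfig, run_pipeline

d = pathlib.Path(tempfile.mkdtemp())
ds = make_toy_dataset(n_seqs=10, n_samples=3, seed=1, out_dir=d)
store = build_store(ds.store_tsv, d / "store.sqlite")
res = run_pipeline(PipelineConfig(
    fasta=str(ds.fasta), out_dir=str(d / "out"), obo=str(ds.obo),
    store=str(store), abundances=str(ds.abundances),
    search_results=str(ds.hits)))
print(res.seq_term_matrix.round(3).head(4))
print("unannotated:", res.unannotated)
```

prints

```
term        E:1  E:2    E:3  E:4    E:5
sequence
C1        0.000  0.0  0.667  0.0  0.333
C2        0.000  0.0  1.000  0.0  0.000
C3        0.000  0.0  0.000  0.0  0.000
C4        0.000  0.0  0.500  0.2  0.300
unannotated: ['C3', 'C5', 'C6', 'C8']
```

Sequence C1 has three homologs whose isolation sources tag "fresh
water" twice and "soil" once, hence weights 2/3 and 1/3; C3's hits all
fail the filtering thresholds, so it carries no environmental
information and is listed in `unannotated_sequences.txt` under its
original name. The run directory also contains the sequence- and
sample–term TSV tables, per-sequence and per-sample Graphviz DOT
graphs of the tagged ontology hierarchy (node fill runs gray → yellow →
orange with increasing weight), the filtered hit table, and a manifest
of all parameters and input checksums.

The same run from the shell:

```sh
envotag seqs.fasta --abundances counts.tsv --search-results hits.tsv \
        --store store.sqlite --obo envo.obo --backtracking \
        --restrict ENVO:00010483 --out-dir out/
```

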