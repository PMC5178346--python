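# Methods

## Pipeline

`envotag` annotates DNA sequences with Environment Ontology (EnvO)
terms mined from the isolation-source metadata of their database
homologs. A run proceeds through fixed, deterministic stages:

1. **Renaming.** FASTA headers are replaced by placeholders `C1`,
   `C2`, … in file order (headers truncated at the first whitespace
   define the original ids; duplicates are an error). All downstream
   stages see only placeholder ids, which sidesteps encoding and
   quoting problems; the bijective name map is written alongside the
   outputs and used to restore original labels in every table.
2. **Abundance filtering (optional).** With a frequency matrix, only
   the *n* sequences with the highest total count across samples are
   kept (default: all). Ties break by file order, for determinism.
3. **Similarity search.** Sequences are searched against a nucleotide
   database. The aligner sits behind a thin contract — any tool
   emitting the standard 12-column tabular layout works — and a
   precomputed results file can be ingested instead. With
   `threads > 1` the FASTA is chopped into near-equal chunks, each
   searched independently, and the outputs concatenated in chunk
   order; chunking provably cannot change the filtered hit table
   because filtering is per-query.
4. **Hit filtering.** A hit survives when e-value ≤ 10⁻⁴, query
   coverage (alignment length / query length) ≥ 0.97 and identity
   ≥ 0.97; survivors are ranked by ascending e-value (ties: descending
   bitscore, then subject id) and truncated to 10 per query. All four
   thresholds are exposed as flags. Coverage is computed on the query
   because inputs are short marker reads, for which query coverage is
   the conventional species-boundary screen. Thresholds apply before
   truncation.
5. **Metadata lookup.** Subject ids are reduced to record identifiers
   (GI digits from the legacy `gi|…|` dialect, otherwise the accession
   token verbatim) and resolved against a local SQLite store mapping
   record id → isolation-source text and optional PubMed id. Records
   without a non-empty isolation source are discarded silently. The
   store schema is versioned and a builder creates stores from
   3-column TSVs; no network access is ever needed at run time.
6. **Tagging.** Isolation sources are tagged by a dictionary NER built
   from term names and EXACT synonyms, minus a stop-list.
7. **Accumulation → backtracking → restriction → normalization**, then
   the sample matrix and outputs (see below).

## Tagging model

Matching is token-based: text is tokenized on non-alphanumeric
boundaries, lowercased, and scanned left to right; at each position the
longest matching token n-gram (up to the longest lexicon entry) wins
and consumes its span. This greedy leftmost-longest rule is verified
in tests against an exhaustive search over all non-overlapping
segmentations on short texts. Surface forms shorter than 3 characters
are excluded to suppress acronym noise; an ambiguous form mapped to
several terms yields one hit per term. No stemming is applied;
conservative plural-"s" stripping exists but is off by default. The
shipped stop-list is a small curated artifact (forms like "field",
"plant", "spring" that collide with record-keeping language); it
removes exact forms only, so "fresh water" survives a stop-listed
"water". Only is_a edges of the ontology are used anywhere; part_of
and other relations carry no clear frequency-propagation semantics for
this purpose and are ignored.

## Count accumulation

Raw counts per sequence accumulate under three strategies. `flat`
(default) sums every tagged occurrence. `unique_isolation` counts each
distinct isolation-source text once per sequence — a guard against one
heavily resubmitted habitat text dominating a composition.
`unique_pubmed_unique_isolation` deduplicates on the (text, PubMed id)
pair, collapsing records that come from the same study; a missing
PubMed id participates as an explicit "absent" marker, so two
pubmed-less records with the same text still collapse. Deduplication
compares texts exactly after trimming outer whitespace and is
case-sensitive, to avoid over-merging legitimately different sources.
Element-wise, `unique_isolation` never exceeds `flat`; the pair-keyed
strategy lies between them only when PubMed ids repeat, and all three
coincide when a sequence's isolation sources are pairwise distinct.

## Transforms and matrices

Optional transforms run accumulate → backtrack → restrict → normalize.
Backtracking adds each term's count once to every is_a ancestor
(multi-parent paths are deduplicated, so a diamond does not double its
sink); restriction keeps only terms at or below a chosen root.
Restriction after backtracking lets ancestors inside the restricted
subtree receive propagated weight; normalizing last keeps every row a
composition, so restriction implies renormalization. Rows of **S** are
divided by their sums; a sequence whose homologs carried no
environmental information keeps an all-zero row and is reported in
`unannotated_sequences.txt`. The sample matrix is the plain product
**N′ = F·S**, row-normalized, with zero rows (empty samples) preserved
and warned about. Term columns are ordered lexicographically for
reproducible files.

## Outputs and numeric choices

TSV tables are written transposed (columns = sequences or samples,
rows = term id + human-readable name) with values at 6 significant
digits — compact and round-trip safe to 10⁻⁶, which the tests check.
DOT graphs contain the weighted terms plus all their ancestors so the
drawn hierarchy is connected upward; fill colors interpolate linearly
in RGB from gray `#c8c8c8` at the minimum recorded weight through
yellow `#ffe800` to orange `#ff8c00` at the maximum (all-equal weights
render gray; zero-weight ancestors are unfilled). Node and edge order
is sorted, so output is byte-stable across runs. PDF rendering is
delegated to external Graphviz. A JSON manifest records every
parameter and input checksum; the search stage is reused on rerun when
the manifest matches and its output exists.

## Synthetic data

The toy-dataset generator emulates the shape of a real run, not its
content: random nucleotide sequences, heavy-tailed (geometric) sample
counts, and a hit file plus metadata store constructed deliberately so
that every code path is exercised — hits failing each threshold
separately, one query with 12 passing hits (testing truncation to 10),
subjects absent from the store, duplicate isolation-source texts with
shared and distinct PubMed ids (separating the three strategies), and
sequences that end up with no environmental information. Because each
record's template and filter fate are fixed by construction, the
generator tabulates the expected per-query counts per strategy by
simple set logic over its own templates and ships them as a
machine-readable expectation file; integration tests compare the real
pipeline against it. All randomness is seeded and confined to the
generator. What the toy data does **not** emulate: real sequence
homology (hit tables are constructed, not aligned), the vocabulary
breadth of a full EnvO release, free-text noise in real isolation
sources (typos, abbreviations, multilingual entries), or realistic
database metadata coverage — so green tests certify the pipeline's
mechanics, not tagging recall on live records. Default problem sizes
(10 sequences × 3 samples, a 5-term ontology) keep every test and the
acceptance script in the seconds range while still covering all
branches.

## Known limitations

Only the isolation-source field is mined; PubMed abstracts are not
retrieved. The NER is a conservative exact-dictionary matcher, so
paraphrased habitat descriptions ("melted ice from a mountain side")
are missed unless a synonym covers them. Counts are evidence
frequencies in database metadata, not habitat probabilities: database
submission bias propagates straight into the matrices. GI numbers are
legacy identifiers; the store accepts accession.version keys for
current records.
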