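# Methods

## Data model

`cohortstore` holds one study cohort per store bundle.  Participants get
dense internal ids `0..N−1` in first-seen order of the clinical CSV; the
external-to-internal mapping is persisted (`id_map.json`) and every export
translates back to external ids.  A clinical fact is
(patient, concept path, value), with exactly one value per
(patient, concept) — duplicates in the input resolve last-wins with a
logged count.  Missing data is the *absence* of a record, not a sentinel;
exports render it as an explicit null.  Concept paths are hierarchical
`/`-delimited strings normalized to a canonical form (leading and trailing
slash, repeated delimiters collapsed).  A concept is consistently numeric
or categorical; mixing types is a hard ETL error naming the concept.

Consent is an ordinary categorical concept under the reserved path
`/_consent/`, one consent-group label per participant, populated at ETL
like any other column.  This makes consent scoping a plain categorical
filter and guarantees the label is available to every export row.

## Phenotype store

Each concept's column carries the patient index plus its inversion (the
numerical or categorical index); the three views of a column are
serialization-level equals — the suite rebuilds the inverted indices from
the patient index and checks identity.  A column is serialized to a
versioned binary layout (magic, version, type tag, entries sorted by
patient id), gzip-compressed (`mtime=0` so pre-encryption bytes are
deterministic) and encrypted as one AES-256-GCM record.  The data file is
the concatenation of these records; `metadata.json` (plaintext, by design —
it is the searchable dictionary) stores per-concept type, observation
count, numeric range or category set, and the record's offset and length.

Numeric range filters take explicit per-bound inclusivity flags.  Both
orientations are supported because feasibility narratives mix them ("BMI
greater than 30" is an exclusive low bound); the default is inclusive on
both ends.

Export walks patients in ascending id order in chunks: each chunk of at
most `chunk_size` rows is written to a temporary file and streamed back, so
peak in-memory rows never exceed the chunk size and output is byte-wise
independent of `chunk_size`; temp files are removed on completion or error.

## Encryption

Records are sealed as `nonce(12) ‖ ciphertext ‖ tag(16)` under
AES-256-GCM with a fresh random 96-bit nonce per record; the 256-bit key
comes from a key file (32 raw bytes or 64 hex characters).  The cipher is
implemented in `_crypto.py` (encrypt-direction AES with T-tables; GHASH via
per-key 8-bit multiplication tables) and validated in the test suite
against vectors produced with OpenSSL's EVP implementation, including the
classic all-zero-key cases.  Throughput is a few hundred KiB/s — ample
because columns are small, compressed before encryption, and decrypted
lazily with caching.  Any tampering or wrong key surfaces as a single
`AuthenticationError` ("bad key or corrupted store"); plaintext is never
released from a record whose tag fails, and a truncated data file affects
only the concepts whose records it clipped.

## Genotype store

Only differences from the reference are stored: a variant with no record
means everyone is homozygous reference.  Two to four zygosity states are
materialized per variant — heterozygous, homozygous, and (behind an ingest
flag) heterozygous no-call and homozygous no-call.  Genotype
classification for a biallelic record: `1/1` → homozygous, `0/1` →
heterozygous, `1/.` → heterozygous no-call, `./.` → homozygous no-call;
`0/.` and `0/0` carry no state (a half-call with no alternate-allele
evidence is treated as non-carrying, since only the four named states
exist).

Masks are dense (one bit per patient, leftmost bit = patient 0) or sparse
(sorted 32-bit ids).  The auto policy goes sparse when
`32 · carriers < n_patients`, the break-even between a 32-bit id per
carrier and one bit per patient; stores beyond 2³¹−1 patients are out of
scope.  Representation is an encoding detail only: every query result is
identical under dense, sparse or mixed masks (property-tested), and
`combine_masks` implements OR/AND as integer bitwise operations, the
decoded results of which commute with set union/intersection.

Variant identity is the six-field comma-joined spec string; `offset` is the
1-based normalized VCF POS and the convention is recorded in the store
header.  Annotations (gene, consequence, severity, allele frequency) are
indexed over variant ids; genomic selection is a conjunction over the
provided axes.  Allele frequency is computed from the stored masks at build
time: `AF = (het + 2·hom) / (2·called)`, where `called` excludes patients
in a no-call state *when no-call masks are materialized*; without them the
store has no missingness information and the denominator is `2N`.  The
frequency axis buckets AF into classes — rare (AF < 0.01), uncommon
(0.01 ≤ AF ≤ 0.05), common (AF > 0.05) — with configurable thresholds.

Partitioning splits a store by chromosome and/or disjoint covering patient
intervals into views that keep global patient ids, so merging per-partition
results is a plain union and equals the unpartitioned result for every
query (tested).  Partitions are an in-process parallelism construct;
multi-server distribution is out of scope.

## Ingest

The VCF is read through pysam (plain or BGZF-compressed).  Annotations come
from a per-alt `ANN=gene|consequence` INFO subfield (one entry per alt, in
alt order) or from a side TSV keyed by the normalized
(chrom, pos, ref, alt); running an annotation pipeline is out of scope.
Multi-allelic sites decompose into one biallelic record per alternate
allele; in each output, alleles equal to that alt map to 1 and every other
called allele — including other alts — maps to 0, so total alternate-allele
count is conserved across the decomposition.

Normalization trims shared trailing bases (extending left from the
reference context when trimming would empty an allele), then shared leading
bases while both alleles keep at least one base.  The result is the
parsimonious, leftmost representation — the standard normal form, verified
against both an exhaustive haplotype-equality oracle (enumerate all
representations of the alternate haplotype, keep the parsimonious ones,
take the leftmost) and `bcftools norm` on random repeat-context variants.
The ETL has no required reference-FASTA input, so during ingest the
record's own REF allele is its context (trimming always happens; extension
beyond the record span requires the optional `reference_fasta` option).

The bundle manifest records input SHA-256 digests, counts (patients,
concepts, biallelic variants), the chosen options and the format version.
ETL is deterministic given inputs and options, up to encryption nonces.

## Query engine

Boolean grammar: conjunction across filters; disjunction within a
categorical filter's label set; disjunction across a genomic filter's
selected variants and requested zygosity states; multiple genomic filters
are independent conjunctive constraints.  An empty query matches the whole
store.  Monotonicity (adding a filter never increases the count) follows
and is property-tested, as is count/export row-count consistency and
filter-order invariance.  Unknown concepts and genes fail validation before
any data is touched.

Canonical query text is JSON with sorted keys and sorted set members under
a versioned schema tag, so label order never changes the canonical form or
its content hash.  A Dataset ID is a random UUID recorded in an append-only
JSON-lines registry together with the canonical text, its hash and the
store-manifest digest — content addressing alone would conflate different
users' intents, so identity is explicit.  Replay re-parses the canonical
text and re-runs it; on a manifest-digest mismatch it refuses unless a
proceed flag is set, in which case it warns and runs.

## Access control

Rules assert query structure only (allowed result types, allowed concept
prefixes, required consent constraints); decisions are deterministic in
(user, canonical query) and never read row data — verified by rebuilding a
store with different values and identical dictionary and asserting
unchanged decisions.  Open tier means aggregate COUNT only, with exact
counts (no small-count flooring or perturbation is applied — a deliberate
simplification).  Consent scoping intersects any existing consent filter
with the user's authorized groups, is idempotent, and an authorized user
with no consent groups scopes to the empty cohort with a logged flag.
Export code runs only after an ALLOW decision.

## Synthetic cohorts

The generator emulates a single dbGaP-style study: numeric concepts are
normal draws (defaults: BMI ~ N(28, 6²), age ~ N(55, 10²)), categorical
concepts are label prevalences (asthma 25% positive), per-concept
missingness defaults to 5%, consent groups are a 60/40 split, and
genotypes follow Hardy–Weinberg proportions at allele frequencies drawn
from Beta(0.4, 2.5) (a right-skewed site-frequency shape), with a 1%
per-allele no-call rate.  Default scale is 100–1,000 patients and 5–40 VCF
sites; sites become two-alt multi-allelic with probability 0.15, with at
least one multi-allelic site guaranteed when five or more sites are drawn.
Everything is a pure function of (config, seed).

The generator also records ground truth from its own bookkeeping — never
through the store or engine — and the suite checks that a naive scan of the
emitted files reproduces those counts, that the engine agrees with a naive
full-scan evaluator (an independent CSV/VCF reader maintained in the test
suite), and that representation and partitioning choices never change a
result.  The four-stage obesity/asthma scenario (BMI > 30, + asthma,
+ FTO variant, + HIGH severity) reproduces the *shape* of a comorbidity
feasibility narrative with nested, non-increasing stage cohorts.

What the generator does not emulate: real marginal distributions or
correlations between phenotypes and genotypes, linkage disequilibrium,
population structure, relatedness, batch effects, or realistic missingness
mechanisms.  Passing tests therefore demonstrate the correctness of the
storage and query machinery, not statistical fidelity to any real study.

## Problem sizes and numerical choices

The test suite and acceptance script run 200 freshly generated cohorts
(mostly 20–150 patients and 5–40 sites, one at 1,000 patients) plus the
400-participant scenario; these sizes exercise every code path — both mask
representations, both annotation routes, partitioned and unpartitioned
evaluation — while keeping a full run in seconds.  Numeric values
round-trip as IEEE doubles; numeric filters compare exactly (no epsilon),
which is correct for the two-decimal values the generator emits and for
dictionary-driven thresholds.  Ties in sorted outputs are broken by patient
id, variant id or lexicographic concept path throughout, so every ordering
is deterministic.

## Known limitations

- Single study per bundle; no shared patient-id space across ingests.
- Write-once stores: updates mean rebuilding (by design, matching the
  load-once model).
- No phasing, structural variants, imputation, or haploid genotypes.
- The pure-Python cipher is not constant-time and is sized for desk-scale
  stores, not terabyte deployments.
- Authorization is local configuration (users.json); there is no identity
  federation or token machinery.
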