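# cohortstore

An encrypted, compressed columnar store and query engine for **combined
clinical + genomic cohort feasibility analysis**, at desk scale.

Biomedical cohort discovery platforms answer questions like *"how many
participants have a body-mass index above 30, carry a variant in FTO, and
have an asthma diagnosis?"* — without handing researchers the raw data.
`cohortstore` implements the storage and query machinery behind that kind of
system as a self-contained Python library and CLI, for methodologists and
engineers who want to study, test or prototype the approach:

- **Phenotype store** — each clinical variable (a `/`-delimited "concept
  path") is one column holding three mutually consistent views: a patient
  index (patient → value), a numerical index (sorted value → patient set)
  and a categorical index (label → patient set).  Every column is serialized,
  GZIP-compressed and then encrypted with AES-256-GCM as an independent
  record; a plaintext JSON metadata file carries the data dictionary and the
  byte offset/length of each column, so dictionary search never decrypts
  patient data.
- **Genotype store** — per variant and per zygosity state
  (heterozygous, homozygous, and optionally the two no-call states), the
  carrying patients are stored either as a dense bitmask over all *n*
  patients (bit *i* ↔ patient *i*, leftmost bit = patient 0: the 12-bit
  mask `100100000100` reads as patients {0, 3, 9}) or, when
  32·|carriers| < *n*, as a sorted list of 32-bit patient ids.  Worst case
  is therefore 4·*n* bits per variant across the four states, and 4 bytes
  per carrier for sparse variants.  Filtering a variant list is one bitwise
  OR per variant.  Variants are identified by the six-field spec string
  `<chrom>,<offset>,<ref>,<alt>,<gene>,<consequence>`; annotations
  (gene, consequence, Ensembl impact severity, allele frequency) are
  indexed over variant ids.
- **ETL** — clinical observations come from a long-format CSV
  (`patient_id,concept_path,value`), genotypes from an annotated VCF.
  Multi-allelic sites are decomposed into biallelic records and each record
  is trimmed and left-aligned to its parsimonious leftmost form before
  storage.  Consequence terms group into the standard Ensembl impact
  categories (HIGH / MODERATE / LOW / MODIFIER).
- **Query engine** — a query is a conjunction of filters (disjunction
  within each filter's value set); results are feasibility COUNTs or
  streaming participant-level DATAFRAMEs whose first columns are always the
  participant id and consent-group label.  Queries canonicalize to sorted
  JSON and can be saved under a **Dataset ID** for exact replay, with a
  warning if the stores changed since.
- **Access control** — authorization asserts the *structure* of a query
  (result type, concept prefixes, consent scope) against per-user Access
  Rules, never row data.  Open-tier users get aggregate counts only;
  authorized users are automatically scoped to their consent groups.
- **Synthetic cohorts** — a deterministic generator emits the CSV/VCF/users
  files plus its own ground-truth counts (Hardy–Weinberg genotypes at
  Beta-distributed allele frequencies), so the whole pipeline is testable
  without any real data.

## Worked example

```python
from cohortstore import (
    CohortConfig, EtlOptions, Query, generate_cohort, run_etl,
)
from cohortstore.query import evaluate_count

key = bytes(range(32))                      # 256-bit store key
fx = generate_cohort(CohortConfig(n_patients=300, seed=7), "fx")
bundle = run_etl(fx.csv_path, fx.vcf_path, key, "store")

q = Query.from_dict({
    "numeric_filters": {"/study/bmi/": {"low": 30, "high": None,
                                        "low_inclusive": False,
                                        "high_inclusive": True}},
    "categorical_filters": {"/study/asthma/": ["positive"]},
    "genomic_filters": [{"gene": "FTO"}],
    "result_type": "COUNT",
})
print(evaluate_count(q, bundle))
```

This prints `17` (seed 7): of 300 synthetic participants, 100 have
BMI > 30, 18 of those also carry the asthma label, and 17 of those
additionally carry an FTO variant — each added filter shrinks the cohort,
never grows it.

The same flow is available from the shell:

```bash
cohortstore gen-fixture --scenario obesity-asthma --seed 3 --out fx
cohortstore --config config.yaml etl --csv fx/phenotypes.csv --vcf fx/cohort.vcf
cohortstore --config config.yaml count query.json --user researcher_all
```

Exit codes: 0 success, 2 usage error, 3 authorization denied, 4
data/integrity error.  Denial reasons go to stderr; stdout carries results
only.

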