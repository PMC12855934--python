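"""Combined phenotype + genomic query evaluation and reproducible replay.

A query is a conjunction of filters: each categorical filter is a
disjunction over its labels, each numeric filter a (possibly half-open)
interval, each genomic filter selects variants by gene / severity /
consequence / frequency class and admits any patient carrying any selected
variant in any requested zygosity state.  Adding a filter can therefore
never grow the cohort.  An empty query matches every patient in the store.

Result types are COUNT (a feasibility count) and DATAFRAME (a streaming
participant-level table whose first two columns are always the external
participant id and the consent-group label).  Queries canonicalize to a
sorted, versioned JSON text; saving one issues an opaque Dataset ID under
which the canonical text and the store-manifest digest are recorded in an
append-only JSON-lines registry, so the exact cohort can be reproduced
later — with a warning if the stores have changed since.
"""

from __future__ import annotations

import datetime
import json
import math
import uuid
import warnings
from dataclasses import dataclass, field
from hashlib import sha256
from pathlib import Path
from typing import Iterator, Mapping

from .genotype import CORE_STATES, GenotypeStoreError, ZygosityState
from .ingest import StoreBundle
from .phenotype import CONSENT_CONCEPT, normalize_concept_path

QUERY_SCHEMA = "cohortstore-query/1"

COUNT = "COUNT"
DATAFRAME = "DATAFRAME"


class QueryError(Exception):
    pass


class UnknownDatasetIdError(QueryError):
    pass


class ManifestMismatchError(QueryError):
    """Stores changed since the query was saved; pass proceed=True to run."""


@dataclass(frozen=True)
class NumericFilter:
    low: float = -math.inf
    high: float = math.inf
    low_inclusive: bool = True
    high_inclusive: bool = True


@dataclass(frozen=True)
class GenomicFilter:
    """One genomic constraint; ``None`` axes mean "any"."""

    gene: str | None = None
    severities: frozenset[str] | None = None
    consequences: frozenset[str] | None = None
    frequency: str | None = None
    zygosity: frozenset[ZygosityState] = frozenset(CORE_STATES)


@dataclass
class Query:
    categorical_filters: dict[str, set[str]] = field(default_factory=dict)
    numeric_filters: dict[str, NumericFilter] = field(default_factory=dict)
    required_concepts: list[str] = field(default_factory=list)
    genomic_filters: list[GenomicFilter] = field(default_factory=list)
    export_fields: list[str] = field(default_factory=list)
    result_type: str = COUNT

    def __post_init__(self):
        if self.result_type not in (COUNT, DATAFRAME):
            raise QueryError(f"unknown result type {self.result_type!r}")
        self.categorical_filters = {
            normalize_concept_path(k): set(v)
            for k, v in self.categorical_filters.items()
        }
        self.numeric_filters = {
            normalize_concept_path(k): v
            for k, v in self.numeric_filters.items()
        }
        self.required_concepts = [
            normalize_concept_path(c) for c in self.required_concepts
        ]
        self.export_fields = [
            normalize_concept_path(c) for c in self.export_fields
        ]

    # -- canonical form ------------------------------------------------------

    def to_canonical_dict(self) -> dict:
        def num(x: float):
            return None if math.isinf(x) else float(x)

        return {
            "schema": QUERY_SCHEMA,
            "categorical_filters": {
                k: sorted(v) for k, v in sorted(self.categorical_filters.items())
            },
            "numeric_filters": {
                k: {
                    "low": num(f.low),
                    "high": num(f.high),
                    "low_inclusive": f.low_inclusive,
                    "high_inclusive": f.high_inclusive,
                }
                for k, f in sorted(self.numeric_filters.items())
            },
            "required_concepts": sorted(set(self.required_concepts)),
            "genomic_filters": [
                {
                    "gene": g.gene,
                    "severities": (
                        sorted(g.severities) if g.severities is not None else None
                    ),
                    "consequences": (
                        sorted(g.consequences)
                        if g.consequences is not None
                        else None
                    ),
                    "frequency": g.frequency,
                    "zygosity": sorted(s.value for s in g.zygosity),
                }
                for g in self.genomic_filters
            ],
            "export_fields": list(self.export_fields),
            "result_type": self.result_type,
        }

    def canonical_text(self) -> str:
        return json.dumps(
            self.to_canonical_dict(), sort_keys=True, separators=(",", ":")
        )

    def content_hash(self) -> str:
        return sha256(self.canonical_text().encode()).hexdigest()

    @classmethod
    def from_dict(cls, d: Mapping) -> "Query":
        schema = d.get("schema", QUERY_SCHEMA)
        if schema != QUERY_SCHEMA:
            raise QueryError(f"unsupported query schema {schema!r}")

        def num(x):
            return math.inf if x is None else float(x)

        nf = {}
        for k, f in d.get("numeric_filters", {}).items():
            nf[k] = NumericFilter(
                low=-math.inf if f.get("low") is None else float(f["low"]),
                high=num(f.get("high")),
                low_inclusive=bool(f.get("low_inclusive", True)),
                high_inclusive=bool(f.get("high_inclusive", True)),
            )
        gf = []
        for g in d.get("genomic_filters", []):
            gf.append(
                GenomicFilter(
                    gene=g.get("gene"),
                    severities=(
                        frozenset(g["severities"])
                        if g.get("severities") is not None
                        else None
                    ),
                    consequences=(
                        frozenset(g["consequences"])
                        if g.get("consequences") is not None
                        else None
                    ),
                    frequency=g.get("frequency"),
                    zygosity=frozenset(
                        ZygosityState(s)
                        for s in g.get(
                            "zygosity", [s.value for s in CORE_STATES]
                        )
                    ),
                )
            )
        return cls(
            categorical_filters={
                k: set(v)
                for k, v in d.get("categorical_filters", {}).items()
            },
            numeric_filters=nf,
            required_concepts=list(d.get("required_concepts", [])),
            genomic_filters=gf,
            export_fields=list(d.get("export_fields", [])),
            result_type=d.get("result_type", COUNT),
        )

    @classmethod
    def from_json(cls, text: str) -> "Query":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _validate(query: Query, bundle: StoreBundle) -> None:
    """Fail on unknown concepts/genes before touching any data."""
    store = bundle.phenotype
    for concept in query.categorical_filters:
        if store.metadata_for(concept).value_type != "categorical":
            raise QueryError(f"concept {concept!r} is not categorical")
    for concept in query.numeric_filters:
        if store.metadata_for(concept).value_type != "numeric":
            raise QueryError(f"concept {concept!r} is not numeric")
    for concept in query.required_concepts + query.export_fields:
        store.metadata_for(concept)
    if query.genomic_filters:
        if bundle.genotype is None:
            raise QueryError("bundle has no genotype store")
        genes = bundle.genotype.annotation_index.categorical_index["gene"]
        for g in query.genomic_filters:
            if g.gene is not None and g.gene not in genes:
                raise GenotypeStoreError(f"unknown gene: {g.gene!r}")


def evaluate_cohort(query: Query, bundle: StoreBundle) -> set[int]:
    """Internal patient ids matching every filter (conjunction)."""
    _validate(query, bundle)
    store = bundle.phenotype
    cohort = store.all_patients()
    for concept, labels in query.categorical_filters.items():
        cohort &= store.filter_categorical(concept, labels)
    for concept, f in query.numeric_filters.items():
        cohort &= store.filter_numeric(
            concept, f.low, f.high, f.low_inclusive, f.high_inclusive
        )
    for concept in query.required_concepts:
        cohort &= store.patients_with_concept(concept)
    for g in query.genomic_filters:
        variant_ids = bundle.genotype.select_variants(
            gene=g.gene,
            severities=g.severities,
            consequences=g.consequences,
            frequency=g.frequency,
        )
        cohort &= bundle.genotype.patients_with_variants(
            variant_ids, g.zygosity
        )
    return cohort


def evaluate_count(query: Query, bundle: StoreBundle) -> int:
    if query.result_type != COUNT:
        raise QueryError("evaluate_count requires a COUNT query")
    return len(evaluate_cohort(query, bundle))


EXPORT_HEADER_PREFIX = ["patient_id", "consent"]


def evaluate_export(
    query: Query, bundle: StoreBundle, chunk_size: int = 10_000
) -> Iterator[list]:
    """Stream participant-level rows for the query's cohort.

    The first yielded row is the header.  Columns are the external
    participant id and consent-group label, then the export fields in
    request order; the caller is responsible for authorization.
    """
    if query.result_type != DATAFRAME:
        raise QueryError("evaluate_export requires a DATAFRAME query")
    _validate(query, bundle)
    cohort = sorted(evaluate_cohort(query, bundle))
    store = bundle.phenotype
    fields = [c for c in query.export_fields if c != CONSENT_CONCEPT]
    has_consent = CONSENT_CONCEPT in store.concepts
    concepts = ([CONSENT_CONCEPT] if has_consent else []) + fields
    yield EXPORT_HEADER_PREFIX + fields
    if not cohort:
        return
    for row in store.export_values(cohort, concepts, chunk_size=chunk_size):
        pid = row[0]
        consent = row[1] if has_consent else None
        values = row[2:] if has_consent else row[1:]
        yield [bundle.internal_to_external.get(pid, pid), consent] + values


# ---------------------------------------------------------------------------
# Saved queries (Dataset IDs)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetId:
    value: str

    def __str__(self) -> str:
        return self.value


class QueryRegistry:
    """Append-only JSON-lines registry of saved queries."""

    def __init__(self, path):
        self.path = Path(path)

    def save(self, query: Query, bundle: StoreBundle) -> DatasetId:
        dataset_id = DatasetId(uuid.uuid4().hex)
        entry = {
            "dataset_id": dataset_id.value,
            "query": query.to_canonical_dict(),
            "query_hash": query.content_hash(),
            "manifest_digest": bundle.manifest_digest(),
            "saved_at": datetime.datetime.now(
                datetime.timezone.utc
            ).isoformat(),
        }
        self.path.parent.mkdir(parents=True, exist_ok=True)
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
        return dataset_id

    def lookup(self, dataset_id) -> dict:
        wanted = str(dataset_id)
        if self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                for line in fh:
                    if not line.strip():
                        continue
                    entry = json.loads(line)
                    if entry["dataset_id"] == wanted:
                        return entry
        raise UnknownDatasetIdError(f"unknown Dataset ID: {wanted}")


def save_query(
    query: Query, registry: QueryRegistry, bundle: StoreBundle
) -> DatasetId:
    return registry.save(query, bundle)


def replay(
    dataset_id,
    registry: QueryRegistry,
    bundle: StoreBundle,
    proceed_on_mismatch: bool = False,
    chunk_size: int = 10_000,
):
    """Re-run a saved query; COUNT -> int, DATAFRAME -> row iterator.

    A manifest-digest mismatch (the stores changed since saving) raises
    unless ``proceed_on_mismatch`` is set, in which case it warns and runs.
    """
    entry = registry.lookup(dataset_id)
    if entry["manifest_digest"] != bundle.manifest_digest():
        message = (
            f"Dataset ID {dataset_id}: store manifest digest changed since "
            "the query was saved; results may differ"
        )
        if not proceed_on_mismatch:
            raise ManifestMismatchError(message)
        warnings.warn(message, stacklevel=2)
    query = Query.from_dict(entry["query"])
    if query.result_type == COUNT:
        return evaluate_count(query, bundle)
    return evaluate_export(query, bundle, chunk_size=chunk_size)
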