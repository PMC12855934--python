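"""Columnar clinical store: a metadata file plus an encrypted data file.

Each clinical variable (a "concept", named by a hierarchical ``/``-delimited
path) is one column.  The metadata file is a plaintext JSON dictionary —
concept paths, value types, observation counts, value ranges/category sets,
and the byte offset and length of each concept's record in the data file —
kept unencrypted so that dictionary search never touches patient data.  The
data file holds one independent record per concept: the serialized column
(patient index plus the derived numerical or categorical index) gzip-
compressed and then AES-GCM-encrypted.

Filtering uses the numerical/categorical index of a concept to produce
patient-id sets; export walks the patient index per concept, spilling rows
to temporary files so that at most ``chunk_size`` rows are ever held in
memory.
"""

from __future__ import annotations

import bisect
import csv
import json
import logging
import math
import re
import struct
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from . import _crypto

logger = logging.getLogger(__name__)

FORMAT_VERSION = 1
_COLUMN_MAGIC = b"CSC1"
METADATA_FILE = "metadata.json"
DATA_FILE = "data.bin"

#: reserved concept carrying each participant's consent-group label
CONSENT_CONCEPT = "/_consent/"

NUMERIC = "numeric"
CATEGORICAL = "categorical"


class PhenotypeStoreError(Exception):
    pass


class UnknownConceptError(PhenotypeStoreError, KeyError):
    def __init__(self, concept_path: str):
        super().__init__(f"unknown concept: {concept_path!r}")
        self.concept_path = concept_path


class StoreIntegrityError(PhenotypeStoreError):
    """Authenticated decryption failed for a concept record."""


def normalize_concept_path(path: str) -> str:
    """Canonical concept path: leading+trailing '/', repeats collapsed."""
    if not path or not path.strip("/"):
        raise ValueError(f"empty concept path: {path!r}")
    return "/" + re.sub("/+", "/", path.strip("/")) + "/"


@dataclass(frozen=True)
class ObservationRecord:
    """One clinical fact: (internal patient id, concept, value)."""

    patient_id: int
    concept_path: str
    value: float | str

    @property
    def is_numeric(self) -> bool:
        return isinstance(self.value, (int, float)) and not isinstance(
            self.value, bool
        )


@dataclass
class ConceptMetadata:
    concept_path: str
    value_type: str  # numeric | categorical
    observation_count: int
    numeric_range: tuple[float, float] | None
    category_set: list[str] | None
    offset: int
    length: int


@dataclass
class ConceptColumn:
    """The three mutually consistent per-concept views.

    ``patient_index`` maps patient id -> value; the numerical index is the
    sorted (value -> patient ids) inversion for numeric concepts and the
    categorical index the (label -> patient ids) inversion for categorical
    ones.
    """

    value_type: str
    patient_index: dict[int, float | str]
    numerical_index: list[tuple[float, list[int]]] = field(
        default_factory=list
    )
    categorical_index: dict[str, list[int]] = field(default_factory=dict)

    @classmethod
    def from_patient_index(
        cls, value_type: str, patient_index: dict
    ) -> "ConceptColumn":
        col = cls(value_type=value_type, patient_index=dict(patient_index))
        inv: dict = {}
        for pid, value in patient_index.items():
            inv.setdefault(value, []).append(pid)
        if value_type == NUMERIC:
            col.numerical_index = [
                (v, sorted(ids)) for v, ids in sorted(inv.items())
            ]
        else:
            col.categorical_index = {
                label: sorted(ids) for label, ids in sorted(inv.items())
            }
        return col


# -- column (de)serialization ------------------------------------------------
#
# Deterministic versioned binary layout so byte-level round-trips are stable:
#   magic | version u8 | type u8 | count u32 | entries sorted by patient id
# followed by the inverted index:
#   n_distinct u32 | per value: value, m u32, m * u32 patient ids

def _pack_str(s: str) -> bytes:
    raw = s.encode("utf-8")
    return struct.pack(">H", len(raw)) + raw


def _unpack_str(buf: bytes, off: int) -> tuple[str, int]:
    (n,) = struct.unpack_from(">H", buf, off)
    off += 2
    return buf[off: off + n].decode("utf-8"), off + n


def serialize_column(col: ConceptColumn) -> bytes:
    out = [
        _COLUMN_MAGIC,
        struct.pack(">BB", FORMAT_VERSION, 0 if col.value_type == NUMERIC else 1),
        struct.pack(">I", len(col.patient_index)),
    ]
    for pid in sorted(col.patient_index):
        value = col.patient_index[pid]
        if col.value_type == NUMERIC:
            out.append(struct.pack(">Id", pid, float(value)))
        else:
            out.append(struct.pack(">I", pid) + _pack_str(str(value)))
    if col.value_type == NUMERIC:
        out.append(struct.pack(">I", len(col.numerical_index)))
        for value, ids in col.numerical_index:
            out.append(struct.pack(">dI", value, len(ids)))
            out.append(struct.pack(f">{len(ids)}I", *ids))
    else:
        out.append(struct.pack(">I", len(col.categorical_index)))
        for label in sorted(col.categorical_index):
            ids = col.categorical_index[label]
            out.append(_pack_str(label) + struct.pack(">I", len(ids)))
            out.append(struct.pack(f">{len(ids)}I", *ids))
    return b"".join(out)


def deserialize_column(buf: bytes) -> ConceptColumn:
    if buf[:4] != _COLUMN_MAGIC:
        raise StoreIntegrityError("bad column magic")
    version, type_tag = struct.unpack_from(">BB", buf, 4)
    if version != FORMAT_VERSION:
        raise StoreIntegrityError(f"unsupported column version {version}")
    value_type = NUMERIC if type_tag == 0 else CATEGORICAL
    (count,) = struct.unpack_from(">I", buf, 6)
    off = 10
    patient_index: dict[int, float | str] = {}
    for _ in range(count):
        if value_type == NUMERIC:
            pid, value = struct.unpack_from(">Id", buf, off)
            off += 12
            patient_index[pid] = value
        else:
            (pid,) = struct.unpack_from(">I", buf, off)
            off += 4
            value, off = _unpack_str(buf, off)
            patient_index[pid] = value
    col = ConceptColumn(value_type=value_type, patient_index=patient_index)
    (n_distinct,) = struct.unpack_from(">I", buf, off)
    off += 4
    for _ in range(n_distinct):
        if value_type == NUMERIC:
            value, m = struct.unpack_from(">dI", buf, off)
            off += 12
            ids = list(struct.unpack_from(f">{m}I", buf, off))
            off += 4 * m
            col.numerical_index.append((value, ids))
        else:
            label, off = _unpack_str(buf, off)
            (m,) = struct.unpack_from(">I", buf, off)
            off += 4
            ids = list(struct.unpack_from(f">{m}I", buf, off))
            off += 4 * m
            col.categorical_index[label] = ids
    return col


# -- building ----------------------------------------------------------------

def build_phenotype_store(
    observations: Iterable[ObservationRecord],
    key: bytes,
    out_dir,
    n_patients: int | None = None,
) -> "PhenotypeStore":
    """Group observations per concept, encrypt each column, write the store.

    ``n_patients`` fixes the patient universe size; when omitted it is
    ``max(patient_id) + 1`` over the observations.
    """
    if len(key) != _crypto.KEY_BYTES:
        raise ValueError(
            f"key must be exactly {_crypto.KEY_BYTES} bytes, got {len(key)}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    per_concept: dict[str, dict[int, float | str]] = {}
    types: dict[str, str] = {}
    max_pid = -1
    for rec in observations:
        path = normalize_concept_path(rec.concept_path)
        vtype = NUMERIC if rec.is_numeric else CATEGORICAL
        known = types.setdefault(path, vtype)
        if known != vtype:
            raise PhenotypeStoreError(
                f"concept {path!r} mixes numeric and categorical values"
            )
        per_concept.setdefault(path, {})[rec.patient_id] = (
            float(rec.value) if vtype == NUMERIC else str(rec.value)
        )
        max_pid = max(max_pid, rec.patient_id)
    if n_patients is None:
        n_patients = max_pid + 1
    elif max_pid >= n_patients:
        raise PhenotypeStoreError(
            f"patient id {max_pid} >= n_patients={n_patients}"
        )

    concepts: list[dict] = []
    with open(out_dir / DATA_FILE, "wb") as fh:
        pos = 0
        for path in sorted(per_concept):
            col = ConceptColumn.from_patient_index(
                types[path], per_concept[path]
            )
            record = _crypto.seal_record(key, serialize_column(col))
            fh.write(record)
            values = list(col.patient_index.values())
            concepts.append(
                {
                    "concept_path": path,
                    "value_type": types[path],
                    "observation_count": len(values),
                    "numeric_range": (
                        [min(values), max(values)]
                        if types[path] == NUMERIC
                        else None
                    ),
                    "category_set": (
                        sorted(set(values))
                        if types[path] == CATEGORICAL
                        else None
                    ),
                    "offset": pos,
                    "length": len(record),
                }
            )
            pos += len(record)

    metadata = {
        "format_version": FORMAT_VERSION,
        "n_patients": n_patients,
        "concepts": concepts,
    }
    (out_dir / METADATA_FILE).write_text(
        json.dumps(metadata, indent=1, sort_keys=True)
    )
    return PhenotypeStore.open(
        out_dir / METADATA_FILE, out_dir / DATA_FILE, key
    )


# -- the store handle --------------------------------------------------------

class PhenotypeStore:
    """Lazily decrypting handle: no column is decrypted until referenced."""

    def __init__(self, metadata_path: Path, data_path: Path, key: bytes,
                 metadata: dict):
        self._metadata_path = metadata_path
        self._data_path = data_path
        self._key = key
        self.n_patients: int = metadata["n_patients"]
        self.format_version: int = metadata["format_version"]
        self._concepts: dict[str, ConceptMetadata] = {}
        for c in metadata["concepts"]:
            meta = ConceptMetadata(
                concept_path=c["concept_path"],
                value_type=c["value_type"],
                observation_count=c["observation_count"],
                numeric_range=(
                    tuple(c["numeric_range"]) if c["numeric_range"] else None
                ),
                category_set=c["category_set"],
                offset=c["offset"],
                length=c["length"],
            )
            self._concepts[meta.concept_path] = meta
        self._column_cache: dict[str, ConceptColumn] = {}

    @classmethod
    def open(cls, metadata_path, data_path, key: bytes) -> "PhenotypeStore":
        metadata_path, data_path = Path(metadata_path), Path(data_path)
        if len(key) != _crypto.KEY_BYTES:
            raise ValueError(
                f"key must be exactly {_crypto.KEY_BYTES} bytes, "
                f"got {len(key)}"
            )
        metadata = json.loads(metadata_path.read_text())
        return cls(metadata_path, data_path, key, metadata)

    @property
    def concepts(self) -> dict[str, ConceptMetadata]:
        return dict(self._concepts)

    def metadata_for(self, concept_path: str) -> ConceptMetadata:
        path = normalize_concept_path(concept_path)
        try:
            return self._concepts[path]
        except KeyError:
            raise UnknownConceptError(path) from None

    def column(self, concept_path: str) -> ConceptColumn:
        meta = self.metadata_for(concept_path)
        cached = self._column_cache.get(meta.concept_path)
        if cached is not None:
            return cached
        with open(self._data_path, "rb") as fh:
            fh.seek(meta.offset)
            record = fh.read(meta.length)
        if len(record) != meta.length:
            raise StoreIntegrityError(
                f"concept {meta.concept_path!r}: data file truncated"
            )
        try:
            payload = _crypto.open_record(self._key, record)
        except _crypto.AuthenticationError as exc:
            raise StoreIntegrityError(
                f"concept {meta.concept_path!r}: {exc}"
            ) from exc
        col = deserialize_column(payload)
        self._column_cache[meta.concept_path] = col
        return col

    # -- dictionary ----------------------------------------------------------

    def search_dictionary(self, term: str) -> list[ConceptMetadata]:
        """Case-insensitive substring search over paths and category labels."""
        needle = term.lower()
        hits = []
        for path in sorted(self._concepts):
            meta = self._concepts[path]
            if needle in path.lower() or any(
                needle in label.lower()
                for label in (meta.category_set or ())
            ):
                hits.append(meta)
        return hits

    # -- filters -------------------------------------------------------------

    def filter_numeric(
        self,
        concept_path: str,
        low: float = -math.inf,
        high: float = math.inf,
        low_inclusive: bool = True,
        high_inclusive: bool = True,
    ) -> set[int]:
        meta = self.metadata_for(concept_path)
        if meta.value_type != NUMERIC:
            raise PhenotypeStoreError(
                f"concept {meta.concept_path!r} is categorical, not numeric"
            )
        index = self.column(concept_path).numerical_index
        values = [v for v, _ in index]
        lo = (
            bisect.bisect_left(values, low)
            if low_inclusive
            else bisect.bisect_right(values, low)
        )
        hi = (
            bisect.bisect_right(values, high)
            if high_inclusive
            else bisect.bisect_left(values, high)
        )
        out: set[int] = set()
        for _, ids in index[lo:hi]:
            out.update(ids)
        return out

    def filter_categorical(
        self, concept_path: str, values: Iterable[str]
    ) -> set[int]:
        meta = self.metadata_for(concept_path)
        if meta.value_type != CATEGORICAL:
            raise PhenotypeStoreError(
                f"concept {meta.concept_path!r} is numeric, not categorical"
            )
        index = self.column(concept_path).categorical_index
        out: set[int] = set()
        for label in values:
            ids = index.get(label)
            if ids is None:
                logger.warning(
                    "label %r not present for concept %r",
                    label,
                    meta.concept_path,
                )
                continue
            out.update(ids)
        return out

    def patients_with_concept(self, concept_path: str) -> set[int]:
        """Patients having any observation of the concept."""
        return set(self.column(concept_path).patient_index)

    def all_patients(self) -> set[int]:
        return set(range(self.n_patients))

    # -- export --------------------------------------------------------------

    def export_values(
        self,
        patient_ids: Sequence[int],
        concepts: Sequence[str],
        chunk_size: int = 10_000,
    ) -> Iterator[list]:
        """Stream ``[patient_id, value...]`` rows in ascending patient id.

        Rows are produced in chunks of at most ``chunk_size``: each chunk is
        written to a temporary file and re-read, so peak in-memory rows never
        exceed the chunk size; temp files are removed on completion or error.
        """
        if chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        paths = [normalize_concept_path(c) for c in concepts]
        for p in paths:
            if p not in self._concepts:
                raise UnknownConceptError(p)
        columns = {p: self.column(p).patient_index for p in paths}
        ordered = sorted(set(patient_ids))

        for start in range(0, len(ordered), chunk_size):
            chunk = ordered[start: start + chunk_size]
            with tempfile.NamedTemporaryFile(
                "w+", suffix=".chunk.csv", newline="", delete=True
            ) as tmp:
                writer = csv.writer(tmp)
                for pid in chunk:
                    row: list = [pid]
                    for p in paths:
                        value = columns[p].get(pid)
                        row.append("" if value is None else value)
                    writer.writerow(row)
                tmp.flush()
                tmp.seek(0)
                for raw in csv.reader(tmp):
                    pid = int(raw[0])
                    out: list = [pid]
                    for p, cell in zip(paths, raw[1:]):
                        if cell == "":
                            out.append(None)
                        elif columns[p] and self._concepts[p].value_type == NUMERIC:
                            out.append(float(cell))
                        else:
                            out.append(cell)
                    yield out
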