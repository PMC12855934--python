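"""Bitmask genotype store: per-variant, per-zygosity patient sets.

Genomic data is stored as differences from the reference: a variant that is
absent means every patient is homozygous reference.  For each variant and
each zygosity state the set of carrying patients is kept either as a dense
bit vector over all patients (leftmost bit = patient 0, so the 12-patient
mask ``100100000100`` reads as patients {0, 3, 9}) or, when carriers are few,
as a sorted list of 32-bit patient ids.  The break-even is 32 bits per sparse
id against 1 bit per patient, so a state goes sparse iff
``32 * carriers < n_patients``.

Filtering a variant list is mask algebra: one bitwise OR per variant, with
set bits in the result naming the qualifying patients.  Variant annotations
(gene, consequence, impact severity, allele frequency) are indexed over
variant ids, mirroring the numerical/categorical indices of the phenotype
side, with the variant table mapping each id to its canonical six-field
spec string ``<chrom>,<offset>,<ref>,<alt>,<gene>,<consequence>``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _crypto

FORMAT_VERSION = 1
SPARSE_ID_BITS = 32
COORDINATE_CONVENTION = "1-based"  # offset field equals normalized VCF POS


class GenotypeStoreError(Exception):
    """Problems building, opening or querying a genotype store."""


class ZygosityState(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    HETEROZYGOUS_NOCALL = "heterozygous_nocall"
    HOMOZYGOUS_NOCALL = "homozygous_nocall"


CORE_STATES = (ZygosityState.HETEROZYGOUS, ZygosityState.HOMOZYGOUS)
NOCALL_STATES = (
    ZygosityState.HETEROZYGOUS_NOCALL,
    ZygosityState.HOMOZYGOUS_NOCALL,
)
ALL_STATES = CORE_STATES + NOCALL_STATES


# ---------------------------------------------------------------------------
# Variant specification strings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSpec:
    """Canonical identity of one biallelic, normalized variant."""

    chrom: str
    offset: int  # 1-based, equal to VCF POS after normalization
    ref: str
    alt: str
    gene: str
    consequence: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical: {self.ref!r}")


def parse_variant_spec(s: str) -> VariantSpec:
    fields = s.split(",")
    if len(fields) != 6:
        raise ValueError(f"expected 6 fields, got {len(fields)}: {s!r}")
    chrom, offset, ref, alt, gene, consequence = fields
    return VariantSpec(chrom, int(offset), ref, alt, gene, consequence)


def format_variant_spec(v: VariantSpec) -> str:
    return f"{v.chrom},{v.offset},{v.ref},{v.alt},{v.gene},{v.consequence}"


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantMask:
    """Patient set for one (variant, zygosity state).

    ``dense`` payload is an int whose bit ``n_patients - 1 - i`` flags
    patient ``i`` (so the leftmost/most-significant bit is patient 0);
    ``sparse`` payload is a sorted tuple of patient ids.
    """

    representation: str  # 'dense' | 'sparse'
    n_patients: int
    bits: int = 0
    ids: tuple[int, ...] = ()

    def carrier_count(self) -> int:
        if self.representation == "dense":
            return self.bits.bit_count()
        return len(self.ids)


def encode_mask(
    carriers: Iterable[int],
    n_patients: int,
    policy: str = "auto",
) -> VariantMask:
    """Encode a carrier set, choosing dense or sparse representation.

    ``policy`` is ``auto`` (sparse iff ``32 * |carriers| < n_patients``),
    ``dense`` or ``sparse`` (forced).
    """
    ids = sorted(set(carriers))
    if ids and (ids[0] < 0 or ids[-1] >= n_patients):
        bad = ids[0] if ids[0] < 0 else ids[-1]
        raise ValueError(
            f"patient id {bad} out of range for n_patients={n_patients}"
        )
    if policy not in ("auto", "dense", "sparse"):
        raise ValueError(f"unknown mask policy {policy!r}")
    if policy == "auto":
        policy = (
            "sparse" if SPARSE_ID_BITS * len(ids) < n_patients else "dense"
        )
    if policy == "sparse":
        return VariantMask("sparse", n_patients, ids=tuple(ids))
    bits = 0
    top = n_patients - 1
    for i in ids:
        bits |= 1 << (top - i)
    return VariantMask("dense", n_patients, bits=bits)


def decode_mask(mask: VariantMask) -> list[int]:
    """Sorted patient ids carried by a mask."""
    if mask.representation == "sparse":
        return list(mask.ids)
    if mask.bits == 0:
        return []
    nbytes = (mask.n_patients + 7) // 8
    pad = 8 * nbytes - mask.n_patients
    raw = np.frombuffer(
        (mask.bits << pad).to_bytes(nbytes, "big"), dtype=np.uint8
    )
    positions = np.nonzero(np.unpackbits(raw, count=mask.n_patients))[0]
    return positions.tolist()


def _as_dense_bits(mask: VariantMask) -> int:
    if mask.representation == "dense":
        return mask.bits
    bits = 0
    top = mask.n_patients - 1
    for i in mask.ids:
        bits |= 1 << (top - i)
    return bits


def combine_masks(masks: Sequence[VariantMask], op: str) -> VariantMask:
    """Bitwise OR (union) or AND (intersection) over masks.

    Mixed dense/sparse inputs are fine; the result is re-encoded under the
    auto policy.
    """
    if op not in ("OR", "AND"):
        raise ValueError(f"op must be 'OR' or 'AND', got {op!r}")
    if not masks:
        raise ValueError("combine_masks needs at least one mask")
    n = masks[0].n_patients
    for m in masks[1:]:
        if m.n_patients != n:
            raise ValueError(
                f"mismatched n_patients: {m.n_patients} != {n}"
            )
    acc = _as_dense_bits(masks[0])
    for m in masks[1:]:
        if op == "OR":
            acc |= _as_dense_bits(m)
        else:
            acc &= _as_dense_bits(m)
    dense = VariantMask("dense", n, bits=acc)
    return encode_mask(decode_mask(dense), n, policy="auto")


def mask_storage_size(mask: VariantMask) -> int:
    """Storage footprint in bits under the store's accounting.

    Dense: one bit per patient per state (worst case 4n bits per variant
    across the four zygosity states).  Sparse: one 32-bit id per carrier
    (4 bytes per carrying patient).
    """
    if mask.representation == "dense":
        return mask.n_patients
    return SPARSE_ID_BITS * len(mask.ids)


def _serialize_mask(mask: VariantMask) -> bytes:
    if mask.representation == "dense":
        nbytes = (mask.n_patients + 7) // 8
        pad = 8 * nbytes - mask.n_patients
        return b"D" + (mask.bits << pad).to_bytes(nbytes, "big")
    return b"S" + np.asarray(mask.ids, dtype=">u4").tobytes()


def _deserialize_mask(payload: bytes, n_patients: int) -> VariantMask:
    tag, body = payload[:1], payload[1:]
    if tag == b"D":
        nbytes = (n_patients + 7) // 8
        pad = 8 * nbytes - n_patients
        bits = int.from_bytes(body, "big") >> pad
        return VariantMask("dense", n_patients, bits=bits)
    if tag == b"S":
        ids = tuple(np.frombuffer(body, dtype=">u4").astype(int).tolist())
        return VariantMask("sparse", n_patients, ids=ids)
    raise GenotypeStoreError(f"unknown mask tag {tag!r}")


# ---------------------------------------------------------------------------
# Annotation index over variant ids
# ---------------------------------------------------------------------------

DEFAULT_FREQUENCY_CLASSES = {
    # paper names the frequency axis; class boundaries are configurable
    "rare": (0.0, 0.01, True, False),          # AF < 0.01
    "uncommon": (0.01, 0.05, True, True),      # 0.01 <= AF <= 0.05
    "common": (0.05, 1.0, False, True),        # AF > 0.05
}


@dataclass
class VariantAnnotationIndex:
    """Categorical/numerical indices keyed by variant id.

    ``variant_table[i]`` is the spec string of variant id ``i``; the
    categorical index maps gene / consequence / severity values to sorted
    variant-id lists and the numerical index holds per-variant allele
    frequency.
    """

    variant_table: list[str]
    categorical_index: dict[str, dict[str, list[int]]]
    numerical_index: dict[str, list[float]]  # position = variant id

    @classmethod
    def build(
        cls,
        specs: Sequence[VariantSpec],
        severities: Sequence[str],
        allele_frequencies: Sequence[float],
    ) -> "VariantAnnotationIndex":
        if not (len(specs) == len(severities) == len(allele_frequencies)):
            raise ValueError("specs, severities and AFs must align")
        cat: dict[str, dict[str, list[int]]] = {
            "gene": {}, "consequence": {}, "severity": {}
        }
        for vid, (spec, sev) in enumerate(zip(specs, severities)):
            cat["gene"].setdefault(spec.gene, []).append(vid)
            cat["consequence"].setdefault(spec.consequence, []).append(vid)
            cat["severity"].setdefault(sev, []).append(vid)
        return cls(
            variant_table=[format_variant_spec(s) for s in specs],
            categorical_index=cat,
            numerical_index={"af": [float(f) for f in allele_frequencies]},
        )


def select_variants(
    index: VariantAnnotationIndex,
    gene: str | None = None,
    severities: Iterable[str] | None = None,
    consequences: Iterable[str] | None = None,
    frequency: str | None = None,
    frequency_classes: Mapping[str, tuple] | None = None,
) -> list[int]:
    """Variant ids satisfying every provided criterion (conjunction).

    ``None`` means "any" for each axis.  Unknown genes raise (the dictionary
    knows every gene), unknown consequence terms simply match nothing.
    """
    candidates: set[int] | None = None

    def restrict(ids: Iterable[int]):
        nonlocal candidates
        s = set(ids)
        candidates = s if candidates is None else candidates & s

    if gene is not None:
        if gene not in index.categorical_index["gene"]:
            raise GenotypeStoreError(f"unknown gene: {gene!r}")
        restrict(index.categorical_index["gene"][gene])
    if severities is not None:
        ids: set[int] = set()
        for sev in severities:
            ids.update(index.categorical_index["severity"].get(sev, ()))
        restrict(ids)
    if consequences is not None:
        ids = set()
        for term in consequences:
            ids.update(index.categorical_index["consequence"].get(term, ()))
        restrict(ids)
    if frequency is not None:
        classes = frequency_classes or DEFAULT_FREQUENCY_CLASSES
        if frequency not in classes:
            raise GenotypeStoreError(
                f"unknown frequency class: {frequency!r}"
            )
        lo, hi, lo_inc, hi_inc = classes[frequency]
        afs = index.numerical_index["af"]
        ids = set()
        for vid, af in enumerate(afs):
            if math.isnan(af):
                continue
            above = af >= lo if lo_inc else af > lo
            below = af <= hi if hi_inc else af < hi
            if above and below:
                ids.add(vid)
        restrict(ids)
    if candidates is None:
        return list(range(len(index.variant_table)))
    return sorted(candidates)


# ---------------------------------------------------------------------------
# The store
# ---------------------------------------------------------------------------

_VARIANTS_FILE = "variants.bin"
_MASKS_FILE = "masks.bin"
_OFFSETS_FILE = "mask_offsets.json"
_HEADER_FILE = "genotype_header.json"
_ANNOT_FILE = "annotations.bin"


def build_genotype_store(
    specs: Sequence[VariantSpec],
    state_carriers: Sequence[Mapping[ZygosityState, Iterable[int]]],
    severities: Sequence[str],
    n_patients: int,
    key: bytes,
    out_dir,
    include_nocall: bool = False,
    mask_policy: str = "auto",
) -> "GenotypeStore":
    """Write an encrypted genotype store and return an open handle.

    ``state_carriers[i]`` maps zygosity states to carrier-id iterables for
    variant id ``i``.  Allele frequencies are computed here from the carrier
    sets: ``AF = (het + 2 * hom) / (2 * called)`` with patients in a no-call
    state excluded from the denominator.
    """
    if len(key) != _crypto.KEY_BYTES:
        raise ValueError(f"key must be 32 bytes, got {len(key)}")
    if not (len(specs) == len(state_carriers) == len(severities)):
        raise ValueError("specs, carriers and severities must align")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    states = ALL_STATES if include_nocall else CORE_STATES

    afs: list[float] = []
    offsets: dict[str, list[int]] = {}
    with open(out_dir / _MASKS_FILE, "wb") as fh:
        pos = 0
        for vid, carriers in enumerate(state_carriers):
            per_state: dict[ZygosityState, VariantMask] = {}
            for state in states:
                mask = encode_mask(
                    carriers.get(state, ()), n_patients, policy=mask_policy
                )
                per_state[state] = mask
                record = _crypto.seal_record(key, _serialize_mask(mask))
                fh.write(record)
                offsets[f"{vid}/{state.value}"] = [pos, len(record)]
                pos += len(record)
            afs.append(_allele_frequency_from_masks(per_state, n_patients))

    variants_blob = "\n".join(format_variant_spec(s) for s in specs).encode()
    (out_dir / _VARIANTS_FILE).write_bytes(
        _crypto.seal_record(key, variants_blob)
    )
    annot = json.dumps(
        {"severities": list(severities), "afs": afs}, sort_keys=True
    ).encode()
    (out_dir / _ANNOT_FILE).write_bytes(_crypto.seal_record(key, annot))
    header = {
        "format_version": FORMAT_VERSION,
        "coordinate_convention": COORDINATE_CONVENTION,
        "n_patients": n_patients,
        "n_variants": len(specs),
        "states": [s.value for s in states],
    }
    (out_dir / _HEADER_FILE).write_text(
        json.dumps(header, indent=1, sort_keys=True)
    )
    (out_dir / _OFFSETS_FILE).write_text(json.dumps(offsets, sort_keys=True))
    return GenotypeStore.open(out_dir, key)


def _allele_frequency_from_masks(
    per_state: Mapping[ZygosityState, VariantMask], n_patients: int
) -> float:
    het = per_state.get(ZygosityState.HETEROZYGOUS)
    hom = per_state.get(ZygosityState.HOMOZYGOUS)
    n_het = het.carrier_count() if het else 0
    n_hom = hom.carrier_count() if hom else 0
    nocall: set[int] = set()
    for st in NOCALL_STATES:
        m = per_state.get(st)
        if m:
            nocall.update(decode_mask(m))
    called = n_patients - len(nocall)
    if called == 0:
        return float("nan")
    return (n_het + 2 * n_hom) / (2 * called)


class GenotypeStore:
    """Lazily decrypting handle over an on-disk genotype store."""

    def __init__(self, directory: Path, key: bytes, header: dict,
                 offsets: dict):
        self._dir = directory
        self._key = key
        self.n_patients: int = header["n_patients"]
        self.n_variants: int = header["n_variants"]
        self.states = tuple(ZygosityState(s) for s in header["states"])
        self.header = header
        self._offsets = offsets
        self._mask_cache: dict[tuple[int, ZygosityState], VariantMask] = {}
        self._annotation_index: VariantAnnotationIndex | None = None

    @classmethod
    def open(cls, directory, key: bytes) -> "GenotypeStore":
        directory = Path(directory)
        header_path = directory / _HEADER_FILE
        if not header_path.exists():
            raise GenotypeStoreError(f"no genotype store at {directory}")
        header = json.loads(header_path.read_text())
        offsets = json.loads((directory / _OFFSETS_FILE).read_text())
        return cls(directory, key, header, offsets)

    # -- annotation ---------------------------------------------------------

    @property
    def annotation_index(self) -> VariantAnnotationIndex:
        if self._annotation_index is None:
            blob = _crypto.open_record(
                self._key, (self._dir / _VARIANTS_FILE).read_bytes()
            )
            lines = blob.decode().split("\n") if blob else []
            specs = [parse_variant_spec(s) for s in lines if s]
            annot = json.loads(
                _crypto.open_record(
                    self._key, (self._dir / _ANNOT_FILE).read_bytes()
                )
            )
            afs = [
                float("nan") if a is None else a for a in annot["afs"]
            ]
            self._annotation_index = VariantAnnotationIndex.build(
                specs, annot["severities"], afs
            )
        return self._annotation_index

    @property
    def variant_table(self) -> list[str]:
        return self.annotation_index.variant_table

    def variant_spec(self, variant_id: int) -> VariantSpec:
        return parse_variant_spec(self.variant_table[variant_id])

    # -- masks --------------------------------------------------------------

    def mask(self, variant_id: int, state: ZygosityState) -> VariantMask:
        if not 0 <= variant_id < self.n_variants:
            raise GenotypeStoreError(f"unknown variant id: {variant_id}")
        if state not in self.states:
            raise GenotypeStoreError(
                f"state {state.value!r} not materialized in this store"
            )
        cached = self._mask_cache.get((variant_id, state))
        if cached is not None:
            return cached
        off, length = self._offsets[f"{variant_id}/{state.value}"]
        with open(self._dir / _MASKS_FILE, "rb") as fh:
            fh.seek(off)
            record = fh.read(length)
        try:
            payload = _crypto.open_record(self._key, record)
        except _crypto.AuthenticationError as exc:
            raise GenotypeStoreError(
                f"variant {variant_id} state {state.value}: {exc}"
            ) from exc
        mask = _deserialize_mask(payload, self.n_patients)
        self._mask_cache[(variant_id, state)] = mask
        return mask

    def patients_with_variants(
        self,
        variant_ids: Iterable[int],
        states: Iterable[ZygosityState] = CORE_STATES,
    ) -> set[int]:
        """Patients carrying ANY listed variant in ANY requested state.

        One OR per (variant, state) mask, as in the bitmask filtering model.
        """
        masks = []
        for vid in variant_ids:
            for state in states:
                if state not in self.states:
                    continue
                masks.append(self.mask(vid, state))
        if not masks:
            return set()
        return set(decode_mask(combine_masks(masks, "OR")))

    def allele_frequency(self, variant_id: int) -> float:
        """AF from stored masks; NaN when no patient has a call."""
        if not 0 <= variant_id < self.n_variants:
            raise GenotypeStoreError(f"unknown variant id: {variant_id}")
        per_state = {st: self.mask(variant_id, st) for st in self.states}
        return _allele_frequency_from_masks(per_state, self.n_patients)

    def select_variants(self, **kwargs) -> list[int]:
        return select_variants(self.annotation_index, **kwargs)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

@dataclass
class GenomicPartition:
    """View of a store restricted to a chromosome subset and patient range.

    Patient ids stay global, so per-partition results merge by plain union.
    """

    store: GenotypeStore
    chroms: frozenset[str] | None  # None = all
    patient_range: tuple[int, int]  # inclusive [lo, hi]
    variant_ids: list[int] = field(default_factory=list)

    def patients_with_variants(
        self,
        variant_ids: Iterable[int],
        states: Iterable[ZygosityState] = CORE_STATES,
    ) -> set[int]:
        lo, hi = self.patient_range
        own = set(self.variant_ids)
        hits = self.store.patients_with_variants(
            [v for v in variant_ids if v in own], states
        )
        return {p for p in hits if lo <= p <= hi}

    def select_variants(self, **kwargs) -> list[int]:
        own = set(self.variant_ids)
        return [
            v for v in self.store.select_variants(**kwargs) if v in own
        ]


def partition_store(
    store: GenotypeStore,
    by_chrom: bool = False,
    patient_splits: Sequence[tuple[int, int]] | None = None,
) -> list[GenomicPartition]:
    """Partition by chromosome and/or disjoint covering patient intervals."""
    n = store.n_patients
    if patient_splits is None:
        splits = [(0, n - 1)] if n else [(0, -1)]
    else:
        splits = [tuple(s) for s in patient_splits]
        ordered = sorted(splits)
        expect = 0
        for lo, hi in ordered:
            if lo != expect or hi < lo - 1:
                raise ValueError(
                    f"patient splits must be disjoint and covering; "
                    f"got {splits}"
                )
            expect = hi + 1
        if expect != n:
            raise ValueError(
                f"patient splits cover 0..{expect - 1}, store has {n}"
            )
    table = store.variant_table
    if by_chrom:
        by: dict[str, list[int]] = {}
        for vid, s in enumerate(table):
            by.setdefault(s.split(",", 1)[0], []).append(vid)
        chrom_groups = [
            (frozenset([c]), vids) for c, vids in sorted(by.items())
        ]
    else:
        chrom_groups = [(None, list(range(len(table))))]
    return [
        GenomicPartition(store, chroms, rng, vids)
        for chroms, vids in chrom_groups
        for rng in splits
    ]


def merge_results(partial_results: Iterable[set[int]]) -> set[int]:
    """Union of per-partition patient sets."""
    out: set[int] = set()
    for part in partial_results:
        out |= part
    return out
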