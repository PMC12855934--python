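"""ETL: read clinical CSV + annotated VCF, build both stores in one pass.

Data flows in once ("loaded once"): long-format clinical observations from a
``patient_id,concept_path,value`` CSV and genotypes from a VCF whose
alternate alleles carry gene/consequence annotations (an ``ANN`` INFO
subfield with one ``gene|consequence`` entry per alt, or a side TSV keyed by
the normalized ``chrom, pos, ref, alt``).  Multi-allelic sites are
decomposed into one biallelic record per alternate allele and each record is
trimmed and left-aligned to its parsimonious leftmost representation before
it is given a variant spec string.

External subject identifiers (CSV ``patient_id`` values = VCF sample names)
are mapped to dense internal ids 0..N-1 in first-seen CSV order; the mapping
is persisted with the store bundle, together with a manifest recording input
digests, counts and options, so a rebuild from identical inputs is
deterministic apart from encryption nonces.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from . import genotype, phenotype
from .genotype import (
    GenotypeStore,
    VariantSpec,
    ZygosityState,
    build_genotype_store,
)
from .impact import load_impact_table, severity_group  # noqa: F401  (module surface)
from .phenotype import (
    ObservationRecord,
    PhenotypeStore,
    build_phenotype_store,
    normalize_concept_path,
)

logger = logging.getLogger(__name__)

MANIFEST_FILE = "manifest.json"
ID_MAP_FILE = "id_map.json"
PHENOTYPE_DIR = "phenotype"
GENOTYPE_DIR = "genotype"
BUNDLE_FORMAT_VERSION = 1


class IngestError(Exception):
    pass


# ---------------------------------------------------------------------------
# Clinical CSV
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTable:
    """Observations with the external-to-internal patient id mapping."""

    records: list[ObservationRecord]
    id_map: dict[str, int]  # external subject id -> dense internal id
    duplicate_count: int = 0

    @property
    def n_patients(self) -> int:
        return len(self.id_map)


def _sniff_value(raw: str) -> float | str:
    try:
        return float(raw)
    except ValueError:
        return raw


def read_phenotype_csv(path) -> PhenotypeTable:
    """Parse a long-format ``patient_id,concept_path,value`` CSV.

    Values that parse as decimal numbers become numeric observations, all
    others categorical.  External ids become dense internal ids in
    first-seen order.  Duplicate (patient, concept) pairs resolve last-wins;
    the number of overwritten facts is logged and reported.
    """
    path = Path(path)
    id_map: dict[str, int] = {}
    facts: dict[tuple[int, str], float | str] = {}
    order: list[tuple[int, str]] = []
    duplicates = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:3]] != [
            "patient_id",
            "concept_path",
            "value",
        ]:
            raise IngestError(
                f"{path}: expected header 'patient_id,concept_path,value', "
                f"got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise IngestError(
                    f"{path}: malformed row at line {lineno}: "
                    f"expected 3 fields, got {len(row)}"
                )
            ext_id, concept, raw_value = (cell.strip() for cell in row)
            if not ext_id or not concept:
                raise IngestError(
                    f"{path}: malformed row at line {lineno}: "
                    "empty patient_id or concept_path"
                )
            if raw_value == "":
                continue  # missing values are absent records
            try:
                concept = normalize_concept_path(concept)
            except ValueError as exc:
                raise IngestError(
                    f"{path}: malformed row at line {lineno}: {exc}"
                ) from exc
            pid = id_map.setdefault(ext_id, len(id_map))
            key = (pid, concept)
            if key in facts:
                duplicates += 1
            else:
                order.append(key)
            facts[key] = _sniff_value(raw_value)
    if duplicates:
        logger.warning(
            "%s: %d duplicate (patient, concept) facts resolved last-wins",
            path,
            duplicates,
        )
    records = [
        ObservationRecord(pid, concept, facts[(pid, concept)])
        for pid, concept in order
    ]
    return PhenotypeTable(records, id_map, duplicates)


# ---------------------------------------------------------------------------
# Variant decomposition and normalization
# ---------------------------------------------------------------------------

@dataclass
class RawVariantRecord:
    """One VCF site: possibly multi-allelic, possibly unnormalized.

    ``genotypes[i]`` is the allele-index pair of patient/sample ``i`` with
    ``None`` for a missing allele.  ``annotations[k]`` is the
    ``(gene, consequence)`` pair of alt ``k``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: list[str]
    genotypes: list[tuple[int | None, ...]]
    annotations: list[tuple[str, str]] = field(default_factory=list)


def _left_align(
    pos: int, ref: str, alt: str, ctx_seq: str, ctx_start: int
) -> tuple[int, str, str]:
    """Trim shared bases and left-align against the reference context.

    Implements the parsimony + left-alignment normal form: no shared
    trailing bases; shared leading bases removed while both alleles keep at
    least one base; left extension uses the reference context when trimming
    would otherwise empty an allele.
    """
    while ref[-1] == alt[-1]:
        if len(ref) == 1 and len(alt) == 1:
            break
        if len(ref) == 1 or len(alt) == 1:
            if pos <= ctx_start:
                break  # context exhausted; cannot shift further
            base = ctx_seq[pos - 1 - ctx_start]
            ref, alt, pos = base + ref, base + alt, pos - 1
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return pos, ref, alt


def decompose_and_normalize(
    rec: RawVariantRecord,
    ref_context: tuple[str, int] | None = None,
) -> list[RawVariantRecord]:
    """Split a site into biallelic records, each left-aligned and trimmed.

    ``ref_context`` is ``(sequence, 1-based start)`` covering at least the
    record's own REF span; when omitted the record's REF allele is its own
    context (trimming still happens, left extension cannot).  In each
    per-alt output, genotype alleles equal to that alt map to 1, every other
    called allele (reference or another alt) maps to 0, and missing alleles
    stay missing.
    """
    if ref_context is None:
        ctx_seq, ctx_start = rec.ref, rec.pos
    else:
        ctx_seq, ctx_start = ref_context
    span = ctx_seq[rec.pos - ctx_start: rec.pos - ctx_start + len(rec.ref)]
    if rec.pos < ctx_start or span != rec.ref:
        raise IngestError(
            f"{rec.chrom}:{rec.pos} REF {rec.ref!r} disagrees with the "
            f"reference context (context has {span!r})"
        )
    out = []
    for k, alt in enumerate(rec.alts, start=1):
        pos, ref, alt_n = _left_align(
            rec.pos, rec.ref, alt, ctx_seq, ctx_start
        )
        genotypes = [
            tuple(
                None if a is None else (1 if a == k else 0) for a in gt
            )
            for gt in rec.genotypes
        ]
        annotations = (
            [rec.annotations[k - 1]] if rec.annotations else []
        )
        out.append(
            RawVariantRecord(
                chrom=rec.chrom,
                pos=pos,
                ref=ref,
                alts=[alt_n],
                genotypes=genotypes,
                annotations=annotations,
            )
        )
    return out


def classify_zygosity(gt: tuple[int | None, ...]) -> ZygosityState | None:
    """Zygosity state of a biallelic 0/1/missing genotype, if any.

    hom-alt -> HOMOZYGOUS; one alt + one ref -> HETEROZYGOUS; one alt + one
    missing -> HETEROZYGOUS_NOCALL; fully missing -> HOMOZYGOUS_NOCALL.
    A half-call with no alt evidence (``./0``) carries no state, as does
    hom-ref.
    """
    if not gt:
        return None
    alts = sum(1 for a in gt if a == 1)
    missing = sum(1 for a in gt if a is None)
    if missing == len(gt):
        return ZygosityState.HOMOZYGOUS_NOCALL
    if alts == len(gt):
        return ZygosityState.HOMOZYGOUS
    if alts and missing:
        return ZygosityState.HETEROZYGOUS_NOCALL
    if alts:
        return ZygosityState.HETEROZYGOUS
    return None


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def _load_annotation_tsv(path) -> dict[tuple[str, int, str, str], tuple[str, str]]:
    table = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            chrom, pos, ref, alt, gene, consequence = row[:6]
            table[(chrom, int(pos), ref, alt)] = (gene, consequence)
    return table


@dataclass
class VcfData:
    samples: list[str]
    sites: list[RawVariantRecord]
    contexts: list[tuple[str, int] | None]
    side_table: dict | None


def read_vcf(
    vcf_path,
    annotation_tsv=None,
    reference_fasta=None,
) -> VcfData:
    """Read an annotated VCF into raw site records (pre-decomposition)."""
    import pysam

    side_table = (
        _load_annotation_tsv(annotation_tsv) if annotation_tsv else None
    )
    fasta = None
    if reference_fasta is not None:
        from pyfaidx import Fasta

        fasta = Fasta(str(reference_fasta))
    records = []
    contexts = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        samples = list(vf.header.samples)
        for site in vf:
            alts = list(site.alts or ())
            if not alts:
                continue
            ann: list[tuple[str, str]] = []
            if side_table is None:
                raw_ann = site.info.get("ANN")
                if raw_ann is None:
                    raise IngestError(
                        f"{site.chrom}:{site.pos}: no ANN annotation and "
                        "no side annotation table given"
                    )
                if isinstance(raw_ann, str):
                    raw_ann = (raw_ann,)
                if len(raw_ann) != len(alts):
                    raise IngestError(
                        f"{site.chrom}:{site.pos}: {len(raw_ann)} ANN "
                        f"entries for {len(alts)} alts"
                    )
                for entry in raw_ann:
                    gene, consequence = entry.split("|")[:2]
                    ann.append((gene, consequence))
            genotypes = [
                tuple(site.samples[s].get("GT") or (None, None))
                for s in samples
            ]
            rec = RawVariantRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alts=alts,
                genotypes=genotypes,
                annotations=ann,
            )
            if fasta is not None:
                # a window left of the site allows full left-alignment
                start = max(1, site.pos - 500)
                seq = str(
                    fasta[site.chrom][start - 1: site.pos + len(site.ref) - 1]
                )
                contexts.append((seq, start))
            else:
                contexts.append(None)
            records.append(rec)
    # side-table annotations attach after normalization, in run_etl
    if side_table is not None:
        for rec in records:
            rec.annotations = []
    return VcfData(samples, records, contexts, side_table)


# ---------------------------------------------------------------------------
# Bundle + full ETL
# ---------------------------------------------------------------------------

@dataclass
class EtlOptions:
    include_nocall: bool = False
    on_missing_sample: str = "error"  # or "admit"
    annotation_tsv: str | None = None
    reference_fasta: str | None = None
    mask_policy: str = "auto"

    def as_dict(self) -> dict:
        return {
            "include_nocall": self.include_nocall,
            "on_missing_sample": self.on_missing_sample,
            "annotation_tsv": (
                str(self.annotation_tsv) if self.annotation_tsv else None
            ),
            "reference_fasta": (
                str(self.reference_fasta) if self.reference_fasta else None
            ),
            "mask_policy": self.mask_policy,
        }


class StoreBundle:
    """An ETL output directory: both stores, the id map and the manifest."""

    def __init__(self, directory: Path, key: bytes):
        self.directory = Path(directory)
        self.manifest = json.loads(
            (self.directory / MANIFEST_FILE).read_text()
        )
        self.id_map: dict[str, int] = json.loads(
            (self.directory / ID_MAP_FILE).read_text()
        )
        self.internal_to_external = {v: k for k, v in self.id_map.items()}
        pdir = self.directory / PHENOTYPE_DIR
        self.phenotype = PhenotypeStore.open(
            pdir / phenotype.METADATA_FILE, pdir / phenotype.DATA_FILE, key
        )
        gdir = self.directory / GENOTYPE_DIR
        self.genotype = (
            GenotypeStore.open(gdir, key) if gdir.exists() else None
        )

    @property
    def n_patients(self) -> int:
        return self.phenotype.n_patients

    def manifest_digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest, sort_keys=True).encode()
        ).hexdigest()


def open_bundle(directory, key: bytes) -> StoreBundle:
    return StoreBundle(directory, key)


def _sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_etl(
    csv_path,
    vcf_path,
    key: bytes,
    out_dir,
    options: EtlOptions | None = None,
) -> StoreBundle:
    """Extract, transform and load both stores into ``out_dir``.

    Deterministic given (inputs, options) apart from encryption nonces.
    """
    options = options or EtlOptions()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    table = read_phenotype_csv(csv_path)
    n_variants = 0
    if vcf_path is not None:
        vcf = read_vcf(
            vcf_path,
            annotation_tsv=options.annotation_tsv,
            reference_fasta=options.reference_fasta,
        )
        side_table = vcf.side_table
        sample_ids: list[int] = []
        for s in vcf.samples:
            if s not in table.id_map:
                if options.on_missing_sample == "error":
                    raise IngestError(
                        f"VCF sample {s!r} absent from the clinical CSV"
                    )
                table.id_map[s] = len(table.id_map)
            sample_ids.append(table.id_map[s])
        n_patients = table.n_patients

        specs: list[VariantSpec] = []
        carriers: list[dict[ZygosityState, list[int]]] = []
        severities: list[str] = []
        impact_table = load_impact_table()
        for site, ctx in zip(vcf.sites, vcf.contexts):
            for bi in decompose_and_normalize(site, ctx):
                alt = bi.alts[0]
                if side_table is not None:
                    try:
                        gene, consequence = side_table[
                            (bi.chrom, bi.pos, bi.ref, alt)
                        ]
                    except KeyError:
                        raise IngestError(
                            f"no annotation for "
                            f"{bi.chrom},{bi.pos},{bi.ref},{alt}"
                        ) from None
                else:
                    gene, consequence = bi.annotations[0]
                spec = VariantSpec(
                    bi.chrom, bi.pos, bi.ref, alt, gene, consequence
                )
                by_state: dict[ZygosityState, list[int]] = {}
                for sample_idx, gt in enumerate(bi.genotypes):
                    state = classify_zygosity(gt)
                    if state is None:
                        continue
                    if state in genotype.NOCALL_STATES and not options.include_nocall:
                        continue
                    by_state.setdefault(state, []).append(
                        sample_ids[sample_idx]
                    )
                specs.append(spec)
                carriers.append(by_state)
                severities.append(
                    severity_group(consequence, impact_table)
                )
        n_variants = len(specs)
        build_genotype_store(
            specs,
            carriers,
            severities,
            n_patients,
            key,
            out_dir / GENOTYPE_DIR,
            include_nocall=options.include_nocall,
            mask_policy=options.mask_policy,
        )
    else:
        n_patients = table.n_patients

    build_phenotype_store(
        table.records, key, out_dir / PHENOTYPE_DIR, n_patients=n_patients
    )
    (out_dir / ID_MAP_FILE).write_text(
        json.dumps(table.id_map, sort_keys=True)
    )
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "inputs": {
            "csv_sha256": _sha256_file(csv_path),
            "vcf_sha256": (
                _sha256_file(vcf_path) if vcf_path is not None else None
            ),
        },
        "counts": {
            "n_patients": n_patients,
            "n_concepts": len(
                {normalize_concept_path(r.concept_path) for r in table.records}
            ),
            "n_variants": n_variants,
            "duplicate_facts": table.duplicate_count,
        },
        "options": options.as_dict(),
        "coordinate_convention": genotype.COORDINATE_CONVENTION,
    }
    (out_dir / MANIFEST_FILE).write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    return StoreBundle(out_dir, key)
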