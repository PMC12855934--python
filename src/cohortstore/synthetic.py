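"""Deterministic synthetic cohorts: clinical CSV + annotated VCF + users.

The generator emulates the shape of a dbGaP-style study — a long-format
clinical table (numeric concepts drawn from normal distributions,
categorical concepts from label prevalences, one consent-group label per
participant) and a jointly keyed VCF whose genotypes follow Hardy-Weinberg
proportions at per-variant allele frequencies drawn from a Beta
distribution.  Every output byte is a pure function of the configuration
(including its seed).

Alongside the raw files the generator records its own ground truth: for a
set of query templates it counts the matching participants from its
in-memory bookkeeping, never through the store or query engine, so engine
results can be checked against an independent tally.  A naive scan of the
emitted files reproduces the same numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .impact import severity_group
from .phenotype import CONSENT_CONCEPT

VCF_NAME = "cohort.vcf"
CSV_NAME = "phenotypes.csv"
USERS_NAME = "users.json"
TRUTH_NAME = "ground_truth.json"


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ConceptSpec:
    path: str
    kind: str  # 'numeric' | 'categorical'
    mean: float = 0.0
    sd: float = 1.0
    labels: tuple[tuple[str, float], ...] = ()  # (label, probability)
    missing_rate: float = 0.05


def _default_concepts() -> tuple[ConceptSpec, ...]:
    return (
        ConceptSpec("/study/bmi/", "numeric", mean=28.0, sd=6.0),
        ConceptSpec("/study/age/", "numeric", mean=55.0, sd=10.0),
        ConceptSpec(
            "/study/asthma/",
            "categorical",
            labels=(("positive", 0.25), ("negative", 0.75)),
        ),
        ConceptSpec(
            "/study/sex/",
            "categorical",
            labels=(("Female", 0.5), ("Male", 0.5)),
            missing_rate=0.0,
        ),
    )


@dataclass
class CohortConfig:
    n_patients: int = 300
    concepts: tuple[ConceptSpec, ...] = field(
        default_factory=_default_concepts
    )
    n_variants: int = 20  # VCF site rows (some become multi-allelic)
    af_beta: tuple[float, float] = (0.4, 2.5)
    fixed_afs: Mapping[int, float] = field(default_factory=dict)
    genes: tuple[str, ...] = ("FTO", "CHD8", "APOE", "TP53", "BRCA2")
    consequences: tuple[str, ...] = (
        "stop_gained",
        "missense_variant",
        "synonymous_variant",
        "intron_variant",
        "splice_acceptor_variant",
        "5_prime_UTR_variant",
    )
    chroms: tuple[str, ...] = ("1", "16")
    consent_groups: tuple[tuple[str, float], ...] = (
        ("study.c1", 0.6),
        ("study.c2", 0.4),
    )
    no_call_rate: float = 0.01
    multiallelic_fraction: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.n_variants < 0:
            raise ConfigError("n_variants must be non-negative")
        for name, p in list(self.consent_groups):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"bad probability for {name}: {p}")
        for c in self.concepts:
            if c.kind not in ("numeric", "categorical"):
                raise ConfigError(f"bad concept kind {c.kind!r}")
            if not 0.0 <= c.missing_rate <= 1.0:
                raise ConfigError("missing_rate must be in [0, 1]")
            for label, p in c.labels:
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"bad probability for {label}: {p}")
        if not 0.0 <= self.no_call_rate <= 1.0:
            raise ConfigError("no_call_rate must be in [0, 1]")


@dataclass
class Truth:
    """Generator-side bookkeeping, independent of any store."""

    external_ids: list[str]
    consent: dict[int, str]  # internal id -> label
    phenotypes: dict[str, dict[int, float | str]]  # concept -> pid -> value
    variant_specs: list[str]  # biallelic, post-decomposition order
    variant_states: list[dict[str, set[int]]]  # per variant: state -> pids
    severities: list[str]


@dataclass
class CohortFixture:
    directory: Path
    csv_path: Path
    vcf_path: Path
    users_path: Path
    truth_path: Path
    ground_truth: dict
    truth: Truth
    config: CohortConfig


def _sample_concept(rng, spec: ConceptSpec, n: int):
    present = rng.random(n) >= spec.missing_rate
    if spec.kind == "numeric":
        values = np.round(rng.normal(spec.mean, spec.sd, size=n), 2)
        return present, values
    labels = [l for l, _ in spec.labels]
    probs = np.array([p for _, p in spec.labels], dtype=float)
    probs = probs / probs.sum()
    values = rng.choice(labels, size=n, p=probs)
    return present, values


def _genotype_string(gt: tuple) -> str:
    return "/".join("." if a is None else str(a) for a in gt)


def generate_cohort(config: CohortConfig, out_dir) -> CohortFixture:
    """Write CSV + VCF + users.json + ground_truth.json into ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = config.n_patients
    external_ids = [f"P{i:05d}" for i in range(n)]

    # -- consent + phenotypes ----------------------------------------------
    consent_labels = [l for l, _ in config.consent_groups]
    cp = np.array([p for _, p in config.consent_groups], dtype=float)
    cp = cp / cp.sum()
    consent = {
        i: str(label)
        for i, label in enumerate(rng.choice(consent_labels, size=n, p=cp))
    }
    phenotypes: dict[str, dict[int, float | str]] = {
        CONSENT_CONCEPT: dict(consent)
    }
    for spec in config.concepts:
        present, values = _sample_concept(rng, spec, n)
        phenotypes[spec.path] = {
            i: (
                float(values[i])
                if spec.kind == "numeric"
                else str(values[i])
            )
            for i in range(n)
            if present[i]
        }

    csv_path = out_dir / CSV_NAME
    with open(csv_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("patient_id,concept_path,value\n")
        for i, ext in enumerate(external_ids):
            fh.write(f"{ext},{CONSENT_CONCEPT},{consent[i]}\n")
            for spec in config.concepts:
                value = phenotypes[spec.path].get(i)
                if value is not None:
                    fh.write(f"{ext},{spec.path},{value}\n")

    # -- variants ------------------------------------------------------------
    bases = ("A", "C", "G", "T")
    sites = []  # (chrom, pos, ref, alts, anns, af_per_alt)
    positions: dict[str, int] = {}
    n_multi = 0
    for s in range(config.n_variants):
        chrom = config.chroms[s % len(config.chroms)]
        pos = positions.get(chrom, 1000) + int(rng.integers(50, 500))
        positions[chrom] = pos
        multi = (
            config.n_variants >= 5
            and (rng.random() < config.multiallelic_fraction or
                 (s == config.n_variants - 1 and n_multi == 0))
        )
        ref = str(rng.choice(bases))
        if multi:
            alts = list(rng.choice([b for b in bases if b != ref], size=2,
                                   replace=False))
            n_multi += 1
        elif rng.random() < 0.15:  # simple already-normalized deletion
            ref = ref + str(rng.choice(bases))
            alts = [ref[0]]
        else:
            alts = [str(rng.choice([b for b in bases if b != ref]))]
        anns = []
        afs = []
        for _ in alts:
            gene = str(rng.choice(config.genes))
            consequence = str(rng.choice(config.consequences))
            anns.append((gene, consequence))
            afs.append(float(rng.beta(*config.af_beta)) / len(alts))
        if s in config.fixed_afs:
            afs = [float(config.fixed_afs[s])] * len(alts)
        total = sum(afs)
        if total > 0.9:
            afs = [a * 0.9 / total for a in afs]
        sites.append((chrom, pos, ref, alts, anns, afs))

    variant_specs: list[str] = []
    variant_states: list[dict[str, set[int]]] = []
    severities: list[str] = []
    vcf_rows = []
    for chrom, pos, ref, alts, anns, afs in sites:
        # per-patient genotypes at the site (allele indices, maybe missing)
        probs = np.array([1.0 - sum(afs)] + afs)
        alleles = rng.choice(len(alts) + 1, size=(n, 2), p=probs)
        miss = rng.random((n, 2)) < config.no_call_rate
        gts = [
            tuple(
                None if miss[i, j] else int(alleles[i, j]) for j in range(2)
            )
            for i in range(n)
        ]
        vcf_rows.append((chrom, pos, ref, alts, anns, gts))
        for k, (alt, (gene, consequence)) in enumerate(
            zip(alts, anns), start=1
        ):
            states: dict[str, set[int]] = {
                "heterozygous": set(),
                "homozygous": set(),
                "heterozygous_nocall": set(),
                "homozygous_nocall": set(),
            }
            for i, gt in enumerate(gts):
                n_alt = sum(1 for a in gt if a == k)
                n_miss = sum(1 for a in gt if a is None)
                if n_miss == 2:
                    states["homozygous_nocall"].add(i)
                elif n_alt == 2:
                    states["homozygous"].add(i)
                elif n_alt == 1 and n_miss == 1:
                    states["heterozygous_nocall"].add(i)
                elif n_alt == 1:
                    states["heterozygous"].add(i)
            variant_specs.append(
                f"{chrom},{pos},{ref},{alt},{gene},{consequence}"
            )
            variant_states.append(states)
            severities.append(severity_group(consequence))

    vcf_path = out_dir / VCF_NAME
    with open(vcf_path, "w", encoding="utf-8", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in config.chroms:
            fh.write(f"##contig=<ID={chrom},length=100000000>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,'
            'Description="gene|consequence per alt allele">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(external_ids)
            + "\n"
        )
        for chrom, pos, ref, alts, anns, gts in vcf_rows:
            ann = ",".join(f"{g}|{c}" for g, c in anns)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\t"
                f"ANN={ann}\tGT\t"
                + "\t".join(_genotype_string(gt) for gt in gts)
                + "\n"
            )

    # -- users ---------------------------------------------------------------
    users = {
        "users": [
            {"user_id": "open_user", "tier": "open"},
            {
                "user_id": "researcher_all",
                "tier": "authorized",
                "authorized_consents": consent_labels,
                "rules": [],
            },
            {
                "user_id": "researcher_first_consent",
                "tier": "authorized",
                "authorized_consents": consent_labels[:1],
                "rules": [
                    {
                        "name": "study-concepts-only",
                        "allowed_concept_prefixes": ["/study/"],
                    }
                ],
            },
        ]
    }
    users_path = out_dir / USERS_NAME
    users_path.write_text(json.dumps(users, indent=1, sort_keys=True))

    truth = Truth(
        external_ids=external_ids,
        consent=consent,
        phenotypes=phenotypes,
        variant_specs=variant_specs,
        variant_states=variant_states,
        severities=severities,
    )
    ground_truth = _ground_truth_tables(truth, config)
    truth_path = out_dir / TRUTH_NAME
    truth_path.write_text(json.dumps(ground_truth, indent=1, sort_keys=True))
    return CohortFixture(
        directory=out_dir,
        csv_path=csv_path,
        vcf_path=vcf_path,
        users_path=users_path,
        truth_path=truth_path,
        ground_truth=ground_truth,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Ground-truth query templates
# ---------------------------------------------------------------------------

def _carriers(truth: Truth, variant_ids, states=("heterozygous", "homozygous")):
    out: set[int] = set()
    for vid in variant_ids:
        for state in states:
            out |= truth.variant_states[vid][state]
    return out


def _ground_truth_tables(truth: Truth, config: CohortConfig) -> dict:
    n = len(truth.external_ids)
    templates = []

    def add(name: str, query_dict: dict, cohort: set[int]):
        templates.append(
            {"name": name, "query": query_dict, "count": len(cohort)}
        )

    for path, values in truth.phenotypes.items():
        if path == CONSENT_CONCEPT or not values:
            continue
        sample = next(iter(values.values()))
        if isinstance(sample, str):
            labels = sorted(set(values.values()))
            label = labels[0]
            cohort = {pid for pid, v in values.items() if v == label}
            add(
                f"categorical:{path}",
                {
                    "categorical_filters": {path: [label]},
                    "result_type": "COUNT",
                },
                cohort,
            )
        else:
            cut = float(np.median(list(values.values())))
            cohort = {pid for pid, v in values.items() if v >= cut}
            add(
                f"numeric:{path}",
                {
                    "numeric_filters": {
                        path: {"low": cut, "high": None,
                               "low_inclusive": True,
                               "high_inclusive": True}
                    },
                    "result_type": "COUNT",
                },
                cohort,
            )

    genes_present = sorted(
        {s.split(",")[4] for s in truth.variant_specs}
    )
    if genes_present:
        gene = genes_present[0]
        vids = [
            i
            for i, s in enumerate(truth.variant_specs)
            if s.split(",")[4] == gene
        ]
        add(
            f"gene:{gene}",
            {
                "genomic_filters": [{"gene": gene}],
                "result_type": "COUNT",
            },
            _carriers(truth, vids),
        )
        high_vids = [
            i for i in vids if truth.severities[i] == "HIGH"
        ]
        add(
            f"gene-high:{gene}",
            {
                "genomic_filters": [
                    {"gene": gene, "severities": ["HIGH"]}
                ],
                "result_type": "COUNT",
            },
            _carriers(truth, high_vids),
        )
    return {
        "n_patients": n,
        "consent_counts": {
            label: sum(1 for v in truth.consent.values() if v == label)
            for label in {l for l, _ in config.consent_groups}
        },
        "n_biallelic_variants": len(truth.variant_specs),
        "templates": templates,
    }


# ---------------------------------------------------------------------------
# The obesity/asthma narrative fixture
# ---------------------------------------------------------------------------

def scenario_obesity_asthma(seed: int, out_dir) -> CohortFixture:
    """A cohort shaped like the four-stage comorbidity narrative.

    Stage 1 filters body-mass index above 30, stage 2 adds an asthma label,
    stage 3 adds carriage of any variant in an FTO-labelled gene and stage 4
    restricts those variants to HIGH impact.  The stage cohorts are nested,
    so their ground-truth counts are non-increasing.
    """
    config = CohortConfig(
        n_patients=400,
        concepts=(
            ConceptSpec("/study/bmi/", "numeric", mean=29.0, sd=5.0,
                        missing_rate=0.02),
            ConceptSpec(
                "/study/asthma/",
                "categorical",
                labels=(("positive", 0.35), ("negative", 0.65)),
                missing_rate=0.02,
            ),
        ),
        n_variants=10,
        genes=("FTO", "CHD8", "APOE"),
        consequences=("missense_variant", "synonymous_variant",
                      "intron_variant"),
        af_beta=(2.0, 4.0),
        no_call_rate=0.0,
        multiallelic_fraction=0.2,
        seed=seed,
    )
    fixture = generate_cohort(config, out_dir)
    # rewrite the first three biallelic variants as FTO with one HIGH
    # consequence, so the narrative's genomic stages are well-populated
    truth = fixture.truth
    overrides = {0: ("FTO", "stop_gained"), 1: ("FTO", "intron_variant"),
                 2: ("FTO", "intron_variant")}
    _apply_annotation_overrides(fixture, overrides)

    bmi = truth.phenotypes["/study/bmi/"]
    asthma = truth.phenotypes["/study/asthma/"]
    stage1 = {pid for pid, v in bmi.items() if v > 30}
    stage2 = stage1 & {pid for pid, v in asthma.items() if v == "positive"}
    fto_vids = [
        i
        for i, s in enumerate(truth.variant_specs)
        if s.split(",")[4] == "FTO"
    ]
    stage3 = stage2 & _carriers(truth, fto_vids)
    high_vids = [i for i in fto_vids if truth.severities[i] == "HIGH"]
    stage4 = stage3 & _carriers(truth, high_vids)

    stages = []
    base = {
        "numeric_filters": {
            "/study/bmi/": {"low": 30, "high": None,
                            "low_inclusive": False, "high_inclusive": True}
        },
        "result_type": "COUNT",
    }
    stages.append({"name": "bmi_gt_30", "query": json.loads(json.dumps(base)),
                   "count": len(stage1)})
    base["categorical_filters"] = {"/study/asthma/": ["positive"]}
    stages.append({"name": "plus_asthma",
                   "query": json.loads(json.dumps(base)),
                   "count": len(stage2)})
    base["genomic_filters"] = [{"gene": "FTO"}]
    stages.append({"name": "plus_fto_variant",
                   "query": json.loads(json.dumps(base)),
                   "count": len(stage3)})
    base["genomic_filters"] = [{"gene": "FTO", "severities": ["HIGH"]}]
    stages.append({"name": "plus_high_severity",
                   "query": json.loads(json.dumps(base)),
                   "count": len(stage4)})

    fixture.ground_truth["scenario_stages"] = stages
    fixture.truth_path.write_text(
        json.dumps(fixture.ground_truth, indent=1, sort_keys=True)
    )
    return fixture


def _apply_annotation_overrides(
    fixture: CohortFixture, overrides: Mapping[int, tuple[str, str]]
) -> None:
    """Rewrite gene/consequence of chosen biallelic variants in truth + VCF."""
    truth = fixture.truth
    # map biallelic index -> (site order) by walking specs against VCF rows
    new_specs = list(truth.variant_specs)
    for vid, (gene, consequence) in overrides.items():
        chrom, pos, ref, alt, _, _ = new_specs[vid].split(",")
        new_specs[vid] = f"{chrom},{pos},{ref},{alt},{gene},{consequence}"
        truth.severities[vid] = severity_group(consequence)
    truth.variant_specs = new_specs

    # rebuild the VCF ANN fields to match
    spec_by_site: dict[tuple[str, str, str], dict[str, tuple[str, str]]] = {}
    for s in new_specs:
        chrom, pos, ref, alt, gene, consequence = s.split(",")
        spec_by_site.setdefault((chrom, pos, ref), {})[alt] = (
            gene,
            consequence,
        )
    lines = fixture.vcf_path.read_text().splitlines()
    out = []
    for line in lines:
        if line.startswith("#"):
            out.append(line)
            continue
        fields = line.split("\t")
        chrom, pos, _, ref, alt_field = fields[:5]
        alts = alt_field.split(",")
        per_alt = spec_by_site[(chrom, pos, ref)]
        ann = ",".join(
            "|".join(per_alt[a]) for a in alts
        )
        fields[7] = f"ANN={ann}"
        out.append("\t".join(fields))
    fixture.vcf_path.write_text("\n".join(out) + "\n")
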