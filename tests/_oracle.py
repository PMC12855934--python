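"""Naive full-scan evaluator over the raw CSV/VCF fixture files.

Deliberately independent of the package's store and query machinery: the
CSV is read with the stdlib csv module, the VCF with line splitting, and
every filter is evaluated by scanning plain dictionaries.  Only the bundled
consequence->impact data table is shared with the package (it is data, not
code).
"""

from __future__ import annotations

import csv
import math
from importlib import resources

_IMPACT = None


def impact_table() -> dict[str, str]:
    global _IMPACT
    if _IMPACT is None:
        text = (
            resources.files("cohortstore")
            .joinpath("data/consequence_impact.tsv")
            .read_text()
        )
        _IMPACT = dict(
            line.split("\t")
            for line in text.splitlines()
            if line and not line.startswith("#")
        )
    return _IMPACT


def read_csv(csv_path):
    """patient order, and concept -> {pid: typed value}."""
    ids: dict[str, int] = {}
    pheno: dict[str, dict[int, object]] = {}
    with open(csv_path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)
        for ext, concept, value in reader:
            pid = ids.setdefault(ext, len(ids))
            try:
                typed: object = float(value)
            except ValueError:
                typed = value
            pheno.setdefault(concept, {})[pid] = typed
    return ids, pheno


def read_vcf(vcf_path, ids):
    """Biallelic variant dicts in decomposition order."""
    variants = []
    with open(vcf_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                sample_pids = [ids[s] for s in fields[9:]]
                continue
            chrom, pos, _, ref, alt_field = fields[:5]
            info = fields[7]
            anns = []
            for part in info.split(";"):
                if part.startswith("ANN="):
                    anns = [e.split("|") for e in part[4:].split(",")]
            alts = alt_field.split(",")
            gts = []
            for cell in fields[9:]:
                gt = cell.split(":")[0].replace("|", "/").split("/")
                gts.append(
                    tuple(None if a == "." else int(a) for a in gt)
                )
            for k, alt in enumerate(alts, start=1):
                gene, consequence = anns[k - 1][0], anns[k - 1][1]
                states = {
                    "heterozygous": set(),
                    "homozygous": set(),
                    "heterozygous_nocall": set(),
                    "homozygous_nocall": set(),
                }
                for pid, gt in zip(sample_pids, gts):
                    n_alt = sum(1 for a in gt if a == k)
                    n_miss = sum(1 for a in gt if a is None)
                    if n_miss == len(gt):
                        states["homozygous_nocall"].add(pid)
                    elif n_alt == len(gt):
                        states["homozygous"].add(pid)
                    elif n_alt and n_miss:
                        states["heterozygous_nocall"].add(pid)
                    elif n_alt:
                        states["heterozygous"].add(pid)
                variants.append(
                    {
                        "chrom": chrom,
                        "pos": int(pos),
                        "ref": ref,
                        "alt": alt,
                        "gene": gene,
                        "consequence": consequence,
                        "severity": impact_table().get(
                            consequence, "MODIFIER"
                        ),
                        "states": states,
                    }
                )
    return variants


FREQ_CLASSES = {
    "rare": lambda af: af < 0.01,
    "uncommon": lambda af: 0.01 <= af <= 0.05,
    "common": lambda af: af > 0.05,
}


def allele_frequency(variant, n_patients, include_nocall):
    """AF under the store's accounting (no-call masks optional)."""
    states = variant["states"]
    het = len(states["heterozygous"])
    hom = len(states["homozygous"])
    if include_nocall:
        nocall = states["heterozygous_nocall"] | states["homozygous_nocall"]
        called = n_patients - len(nocall)
    else:
        called = n_patients
    if called == 0:
        return math.nan
    return (het + 2 * hom) / (2 * called)


class NaiveEvaluator:
    """Full-scan evaluation of canonical query dicts on the raw files."""

    def __init__(self, csv_path, vcf_path, include_nocall=False):
        self.ids, self.pheno = read_csv(csv_path)
        self.n = len(self.ids)
        self.variants = read_vcf(vcf_path, self.ids) if vcf_path else []
        self.include_nocall = include_nocall

    def select_variant_ids(self, gf: dict) -> list[int]:
        out = []
        for vid, v in enumerate(self.variants):
            if gf.get("gene") is not None and v["gene"] != gf["gene"]:
                continue
            if (
                gf.get("severities") is not None
                and v["severity"] not in gf["severities"]
            ):
                continue
            if (
                gf.get("consequences") is not None
                and v["consequence"] not in gf["consequences"]
            ):
                continue
            if gf.get("frequency") is not None:
                af = allele_frequency(v, self.n, self.include_nocall)
                if math.isnan(af) or not FREQ_CLASSES[gf["frequency"]](af):
                    continue
            out.append(vid)
        return out

    def cohort(self, query: dict) -> set[int]:
        cohort = set(range(self.n))
        for concept, labels in query.get("categorical_filters", {}).items():
            values = self.pheno.get(concept, {})
            cohort &= {
                pid for pid, v in values.items() if v in set(labels)
            }
        for concept, f in query.get("numeric_filters", {}).items():
            lo = -math.inf if f.get("low") is None else f["low"]
            hi = math.inf if f.get("high") is None else f["high"]
            lo_ok = (
                (lambda v: v >= lo)
                if f.get("low_inclusive", True)
                else (lambda v: v > lo)
            )
            hi_ok = (
                (lambda v: v <= hi)
                if f.get("high_inclusive", True)
                else (lambda v: v < hi)
            )
            values = self.pheno.get(concept, {})
            cohort &= {
                pid
                for pid, v in values.items()
                if isinstance(v, float) and lo_ok(v) and hi_ok(v)
            }
        for concept in query.get("required_concepts", []):
            cohort &= set(self.pheno.get(concept, {}))
        for gf in query.get("genomic_filters", []):
            zyg = gf.get("zygosity") or ["heterozygous", "homozygous"]
            if not self.include_nocall:
                zyg = [z for z in zyg if not z.endswith("nocall")]
            carriers: set[int] = set()
            for vid in self.select_variant_ids(gf):
                for state in zyg:
                    carriers |= self.variants[vid]["states"][state]
            cohort &= carriers
        return cohort

    def count(self, query: dict) -> int:
        return len(self.cohort(query))
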