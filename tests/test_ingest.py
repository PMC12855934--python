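"""ETL: CSV parsing, variant decomposition/normalization, store building."""

import json
import subprocess

import numpy as np
import pytest

from cohortstore import EtlOptions, open_bundle, run_etl
from cohortstore.genotype import ZygosityState
from cohortstore.impact import severity_group
from cohortstore.ingest import (
    IngestError,
    RawVariantRecord,
    classify_zygosity,
    decompose_and_normalize,
    read_phenotype_csv,
)

HET = ZygosityState.HETEROZYGOUS
HOM = ZygosityState.HOMOZYGOUS


# ---------------------------------------------------------------------------
# Clinical CSV
# ---------------------------------------------------------------------------

class TestReadPhenotypeCsv:
    def test_basic_parse_and_id_assignment(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text(
            "patient_id,concept_path,value\n"
            "S2,/a/bmi/,30.5\n"
            "S1,/a/asthma/,positive\n"
        )
        table = read_phenotype_csv(f)
        assert len(table.records) == 2
        assert table.id_map == {"S2": 0, "S1": 1}
        bmi, asthma = table.records
        assert bmi.value == 30.5 and bmi.is_numeric
        assert asthma.value == "positive" and not asthma.is_numeric

    def test_bad_row_error_names_line(self, tmp_path):
        lines = ["patient_id,concept_path,value"]
        lines += [f"S{i},/a/x/,{i}" for i in range(15)]
        lines.append("only_one_field")
        f = tmp_path / "p.csv"
        f.write_text("\n".join(lines) + "\n")
        with pytest.raises(IngestError, match="17"):
            read_phenotype_csv(f)

    def test_duplicate_last_wins_with_count(self, tmp_path, caplog):
        f = tmp_path / "p.csv"
        f.write_text(
            "patient_id,concept_path,value\n"
            "S1,/a/bmi/,20\nS1,/a/bmi/,25\nS1,/a/bmi/,30\n"
        )
        with caplog.at_level("WARNING"):
            table = read_phenotype_csv(f)
        assert table.duplicate_count == 2
        assert [r.value for r in table.records] == [30.0]
        assert "2" in caplog.text

    def test_wrong_header_rejected(self, tmp_path):
        f = tmp_path / "p.csv"
        f.write_text("id,path,val\nS1,/a/,1\n")
        with pytest.raises(IngestError, match="header"):
            read_phenotype_csv(f)


# ---------------------------------------------------------------------------
# Decomposition + normalization
# ---------------------------------------------------------------------------

def variant(chrom, pos, ref, alts, genotypes=(), anns=None):
    return RawVariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=list(alts),
        genotypes=list(genotypes),
        annotations=list(anns or [("G", "intron_variant")] * len(alts)),
    )


def normal_form_oracle(hap, ctx_seq, ctx_start):
    """All-representations brute force: the unique parsimonious, leftmost
    (pos, ref, alt) whose substitution into the context yields ``hap``."""
    n = len(ctx_seq)
    candidates = []
    for i in range(n):  # 0-based offset of pos within the context
        if hap[:i] != ctx_seq[:i]:
            break
        for rlen in range(1, n - i + 1):
            tail = ctx_seq[i + rlen:]
            if tail and not hap.endswith(tail):
                continue
            alen = len(hap) - i - len(tail)
            if alen < 1:
                continue
            ref = ctx_seq[i: i + rlen]
            alt = hap[i: i + alen]
            if ref == alt:
                continue
            # parsimony: trailing base shared -> reducible (trim or shift)
            if ref[-1] == alt[-1] and (
                i > 0 or (len(ref) > 1 and len(alt) > 1)
            ):
                continue
            if ref[0] == alt[0] and len(ref) > 1 and len(alt) > 1:
                continue
            candidates.append((ctx_start + i, ref, alt))
    assert candidates, "no parsimonious representation found"
    return min(candidates, key=lambda c: (c[0], len(c[1]), len(c[2])))


def apply_variant(ctx_seq, ctx_start, pos, ref, alt):
    i = pos - ctx_start
    assert ctx_seq[i: i + len(ref)] == ref
    return ctx_seq[:i] + alt + ctx_seq[i + len(ref):]


class TestDecomposeAndNormalize:
    def test_pure_decomposition(self):
        rec = variant("1", 100, "A", ["G", "T"],
                      anns=[("X", "a"), ("Y", "b")])
        out = decompose_and_normalize(rec)
        assert [(r.pos, r.ref, r.alts[0]) for r in out] == [
            (100, "A", "G"),
            (100, "A", "T"),
        ]
        assert [r.annotations for r in out] == [[("X", "a")], [("Y", "b")]]

    def test_repeat_context_left_alignment(self):
        # deleting one C from the CCC run in ACCCT anchors at position 1
        rec = variant("1", 3, "CC", ["C"])
        (out,) = decompose_and_normalize(rec, ref_context=("ACCCT", 1))
        assert (out.pos, out.ref, out.alts[0]) == (1, "AC", "A")

    def test_minimal_snv_is_fixed_point(self):
        rec = variant("1", 3, "C", ["T"])
        (out,) = decompose_and_normalize(rec, ref_context=("ACCCT", 1))
        assert (out.pos, out.ref, out.alts[0]) == (3, "C", "T")
        (again,) = decompose_and_normalize(out, ref_context=("ACCCT", 1))
        assert (again.pos, again.ref, again.alts[0]) == (3, "C", "T")

    def test_ref_context_disagreement_raises(self):
        rec = variant("1", 2, "GG", ["G"])
        with pytest.raises(IngestError, match="disagrees"):
            decompose_and_normalize(rec, ref_context=("ACCCT", 1))

    def test_genotype_remap_convention(self):
        # other alts map to 0 for each per-alt output; missing stays missing
        rec = variant(
            "1", 100, "A", ["G", "T"],
            genotypes=[(1, 2), (0, 1), (2, 2), (None, 2), (0, 0)],
        )
        a, b = decompose_and_normalize(rec)
        assert a.genotypes == [(1, 0), (0, 1), (0, 0), (None, 0), (0, 0)]
        assert b.genotypes == [(0, 1), (0, 0), (1, 1), (None, 1), (0, 0)]

    def test_decomposition_conserves_alt_calls(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n_alts = int(rng.integers(1, 4))
            gts = [
                tuple(int(rng.integers(0, n_alts + 1)) for _ in range(2))
                for _ in range(30)
            ]
            rec = variant("1", 50, "A",
                          [f"{'ACGT'[i]}{'T'*i}" for i in range(1, n_alts + 1)],
                          genotypes=gts)
            out = decompose_and_normalize(rec)
            original = sum(1 for gt in gts for a in gt if a > 0)
            decomposed = sum(
                1 for r in out for gt in r.genotypes for a in gt if a == 1
            )
            assert decomposed == original

    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_shift_oracle_on_repeat_contexts(self, seed):
        """1,000 random variants in repeat-rich contexts match the
        brute-force leftmost parsimonious representation, and the
        normalizer is idempotent on its own output."""
        rng = np.random.default_rng(seed)
        for _ in range(250):
            ctx = "".join(rng.choice(list("AC"), size=18))
            ctx_start = int(rng.integers(1, 50))
            i = int(rng.integers(2, 15))
            rlen = int(rng.integers(1, 4))
            ref = ctx[i: i + rlen]
            alt = "".join(rng.choice(list("AC"),
                                     size=int(rng.integers(1, 4))))
            if alt == ref:
                continue
            pos = ctx_start + i
            rec = variant("1", pos, ref, [alt])
            (out,) = decompose_and_normalize(rec, ref_context=(ctx, ctx_start))
            hap = apply_variant(ctx, ctx_start, pos, ref, alt)
            # haplotype preserved
            assert apply_variant(
                ctx, ctx_start, out.pos, out.ref, out.alts[0]
            ) == hap
            # equals the brute-force normal form
            assert (out.pos, out.ref, out.alts[0]) == normal_form_oracle(
                hap, ctx, ctx_start
            )
            # idempotent
            (again,) = decompose_and_normalize(
                out, ref_context=(ctx, ctx_start)
            )
            assert (again.pos, again.ref, again.alts[0]) == (
                out.pos, out.ref, out.alts[0]
            )

    def test_agrees_with_bcftools_norm(self, tmp_path):
        rng = np.random.default_rng(9)
        ctx = "".join(rng.choice(list("ACGT"), p=[.4, .4, .1, .1], size=60))
        (tmp_path / "ref.fa").write_text(f">1\n{ctx}\n")
        cases = []
        for _ in range(40):
            i = int(rng.integers(1, 50))
            rlen = int(rng.integers(1, 4))
            ref = ctx[i: i + rlen]
            alt = "".join(rng.choice(list("AC"),
                                     size=int(rng.integers(1, 4))))
            if alt != ref:
                cases.append((i + 1, ref, alt))
        cases.sort()
        vcf = ["##fileformat=VCFv4.2", "##contig=<ID=1,length=60>",
               "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
        vcf += [f"1\t{p}\t.\t{r}\t{a}\t.\t.\t." for p, r, a in cases]
        (tmp_path / "in.vcf").write_text("\n".join(vcf) + "\n")
        subprocess.run(
            ["samtools", "faidx", str(tmp_path / "ref.fa")], check=True
        )
        proc = subprocess.run(
            ["bcftools", "norm", "-f", str(tmp_path / "ref.fa"),
             str(tmp_path / "in.vcf")],
            check=True, capture_output=True, text=True,
        )
        expected = [
            (int(f[1]), f[3], f[4])
            for f in (
                line.split("\t")
                for line in proc.stdout.splitlines()
                if not line.startswith("#")
            )
        ]
        got = []
        for p, r, a in cases:
            (out,) = decompose_and_normalize(
                variant("1", p, r, [a]), ref_context=(ctx, 1)
            )
            got.append((out.pos, out.ref, out.alts[0]))
        # bcftools re-sorts records whose positions shifted left
        assert sorted(got) == sorted(expected)


class TestClassifyZygosity:
    @pytest.mark.parametrize(
        "gt,state",
        [
            ((1, 1), HOM),
            ((0, 1), HET),
            ((1, 0), HET),
            ((1, None), ZygosityState.HETEROZYGOUS_NOCALL),
            ((None, 1), ZygosityState.HETEROZYGOUS_NOCALL),
            ((None, None), ZygosityState.HOMOZYGOUS_NOCALL),
            ((0, 0), None),
            ((0, None), None),
        ],
    )
    def test_state_table(self, gt, state):
        assert classify_zygosity(gt) == state


class TestSeverityGroup:
    @pytest.mark.parametrize(
        "term,impact",
        [
            ("stop_gained", "HIGH"),
            ("splice_acceptor_variant", "HIGH"),
            ("missense_variant", "MODERATE"),
            ("synonymous_variant", "LOW"),
            ("intron_variant", "MODIFIER"),
        ],
    )
    def test_known_terms(self, term, impact):
        assert severity_group(term) == impact

    def test_unknown_term_falls_back_to_modifier(self, caplog):
        with caplog.at_level("WARNING"):
            assert severity_group("totally_unknown_term") == "MODIFIER"
        assert "totally_unknown_term" in caplog.text


# ---------------------------------------------------------------------------
# Full ETL
# ---------------------------------------------------------------------------

def write_fixture(tmp_path, extra_sample=None):
    ids = [f"S{i}" for i in range(10)]
    csv_lines = ["patient_id,concept_path,value"]
    for i, s in enumerate(ids):
        csv_lines.append(f"{s},/_consent/,c{i % 2}")
        csv_lines.append(f"{s},/t/bmi/,{20 + i}")
    (tmp_path / "p.csv").write_text("\n".join(csv_lines) + "\n")
    samples = ids + ([extra_sample] if extra_sample else [])
    gts = {s: ["0/1", "0/0", "1/1", "0/0", "1/2" if s == "S0" else "0/0"]
           for s in samples}
    rows = [
        ("1", 100, "A", "G", "GENE1|missense_variant"),
        ("1", 200, "AC", "A", "GENE1|frameshift_variant"),
        ("1", 300, "C", "T", "GENE2|synonymous_variant"),
        ("2", 100, "G", "A", "GENE2|intron_variant"),
        ("2", 250, "T", "A,C",
         "GENE3|stop_gained,GENE3|missense_variant"),  # multi-allelic
    ]
    vcf = ["##fileformat=VCFv4.2",
           "##contig=<ID=1,length=10000>", "##contig=<ID=2,length=10000>",
           '##INFO=<ID=ANN,Number=.,Type=String,Description="x">',
           '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">',
           "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
           + "\t".join(samples)]
    for j, (c, p, r, a, ann) in enumerate(rows):
        vcf.append(
            f"{c}\t{p}\t.\t{r}\t{a}\t.\t.\tANN={ann}\tGT\t"
            + "\t".join(gts[s][j] for s in samples)
        )
    (tmp_path / "g.vcf").write_text("\n".join(vcf) + "\n")
    return tmp_path / "p.csv", tmp_path / "g.vcf"


class TestRunEtl:
    def test_manifest_counts(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        bundle = run_etl(csv_path, vcf_path, key, tmp_path / "store")
        counts = bundle.manifest["counts"]
        assert counts["n_patients"] == 10
        assert counts["n_concepts"] == 2  # consent + bmi
        assert counts["n_variants"] == 6  # 5 sites, one with two alts

    def test_missing_sample_errors_by_name(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path, extra_sample="S99")
        with pytest.raises(IngestError, match="S99"):
            run_etl(csv_path, vcf_path, key, tmp_path / "store")

    def test_missing_sample_admit_option(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path, extra_sample="S99")
        bundle = run_etl(
            csv_path, vcf_path, key, tmp_path / "store",
            EtlOptions(on_missing_sample="admit"),
        )
        assert bundle.manifest["counts"]["n_patients"] == 11
        assert "S99" in bundle.id_map

    def test_multiallelic_genotypes_split_correctly(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        bundle = run_etl(csv_path, vcf_path, key, tmp_path / "store")
        gs = bundle.genotype
        # S0 is 1/2 at the multi-allelic site: het for both alt alleles
        table = gs.variant_table
        vid_a = table.index("2,250,T,A,GENE3,stop_gained")
        vid_c = table.index("2,250,T,C,GENE3,missense_variant")
        s0 = bundle.id_map["S0"]
        assert gs.patients_with_variants([vid_a], {HET}) == {s0}
        assert gs.patients_with_variants([vid_c], {HET}) == {s0}

    def test_deterministic_modulo_nonces(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        b1 = run_etl(csv_path, vcf_path, key, tmp_path / "s1")
        b2 = run_etl(csv_path, vcf_path, key, tmp_path / "s2")
        assert b1.manifest == b2.manifest
        assert b1.manifest_digest() == b2.manifest_digest()
        assert b1.genotype.variant_table == b2.genotype.variant_table
        rows1 = list(b1.phenotype.export_values(range(10), ["/t/bmi/"], 5))
        rows2 = list(b2.phenotype.export_values(range(10), ["/t/bmi/"], 5))
        assert rows1 == rows2
        # ciphertexts differ: fresh nonces per record
        assert (tmp_path / "s1" / "phenotype" / "data.bin").read_bytes() != (
            tmp_path / "s2" / "phenotype" / "data.bin"
        ).read_bytes()

    def test_reopen_bundle(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        run_etl(csv_path, vcf_path, key, tmp_path / "store")
        bundle = open_bundle(tmp_path / "store", key)
        assert bundle.n_patients == 10
        assert bundle.genotype.n_variants == 6

    def test_side_tsv_annotation_route(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        # strip ANN from the VCF, provide annotations via TSV instead
        lines = (tmp_path / "g.vcf").read_text().splitlines()
        stripped = []
        tsv = []
        for line in lines:
            if line.startswith("#"):
                stripped.append(line)
                continue
            f = line.split("\t")
            for alt, ann in zip(f[4].split(","),
                                f[7][4:].split(",")):
                gene, cons = ann.split("|")
                ref, alt_n = f[3], alt
                pos = int(f[1])
                # normalized coordinates for the one indel row
                if (ref, alt_n) == ("AC", "A"):
                    pass  # already parsimonious
                tsv.append(f"{f[0]}\t{pos}\t{ref}\t{alt_n}\t{gene}\t{cons}")
            f[7] = "."
            stripped.append("\t".join(f))
        (tmp_path / "g2.vcf").write_text("\n".join(stripped) + "\n")
        (tmp_path / "ann.tsv").write_text("\n".join(tsv) + "\n")
        bundle = run_etl(
            csv_path, tmp_path / "g2.vcf", key, tmp_path / "store2",
            EtlOptions(annotation_tsv=str(tmp_path / "ann.tsv")),
        )
        assert "2,250,T,A,GENE3,stop_gained" in bundle.genotype.variant_table

    def test_bgzipped_vcf_accepted(self, key, tmp_path):
        import pysam

        csv_path, vcf_path = write_fixture(tmp_path)
        gz = tmp_path / "g.vcf.gz"
        pysam.tabix_compress(str(vcf_path), str(gz), force=True)
        bundle = run_etl(csv_path, gz, key, tmp_path / "store3")
        assert bundle.manifest["counts"]["n_variants"] == 6

    def test_manifest_records_input_digests(self, key, tmp_path):
        csv_path, vcf_path = write_fixture(tmp_path)
        bundle = run_etl(csv_path, vcf_path, key, tmp_path / "store")
        digests = bundle.manifest["inputs"]
        assert len(digests["csv_sha256"]) == 64
        assert len(digests["vcf_sha256"]) == 64
        assert json.loads(
            (tmp_path / "store" / "manifest.json").read_text()
        ) == bundle.manifest
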