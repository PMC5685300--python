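"""Allele counting against a brute-force pileup oracle, X and gold-standard F."""

from __future__ import annotations

import random

import pytest

from fetalfrac.counting import (
    ActualFractionResult,
    CountFilters,
    LocusAlleleCounts,
    compute_actual_fraction,
    count_alleles,
    read_counts,
    summarize_nonmaternal,
    write_counts,
)
from fetalfrac.panel import GenotypeRecord, HomozygousPanel, PanelEntry, SnpLocus

from conftest import SAM_HEADER, sam_line
from pileup_oracle import oracle_counts


def _by_pos(counts):
    return {(c.locus.chrom, c.locus.pos): c for c in counts}


class TestCountAlleles:
    def test_manual_pileup_three_reads(self, write_sam, toy_panel):
        # 3 reads covering chr1:10000 (maternal A) carrying A, A, G
        path, _ = write_sam(
            sam_line("r1", pos=9990, seq="A" * 20),
            sam_line("r2", pos=9995, seq="A" * 20),
            sam_line("r3", pos=10000, seq="G" + "A" * 19),
        )
        counts = _by_pos(count_alleles(path, toy_panel))
        c = counts[("1", 10000)]
        assert c.n_maternal == 2 and c.n_nonmaternal == 1 and c.n_discarded == 0

    def test_n_base_discarded(self, write_sam, toy_panel):
        path, _ = write_sam(sam_line("r1", pos=10000, seq="N" + "A" * 19))
        c = _by_pos(count_alleles(path, toy_panel))[("1", 10000)]
        assert c.depth == 0 and c.n_discarded == 1

    def test_low_quality_base_discarded(self, write_sam, toy_panel):
        # locus base at Q10 (ASCII '+'), rest Q40
        path, _ = write_sam(
            sam_line("r1", pos=10000, seq="G" + "A" * 19, qual="+" + "I" * 19)
        )
        c = _by_pos(count_alleles(path, toy_panel))[("1", 10000)]
        assert c.n_nonmaternal == 0 and c.n_discarded == 1

    def test_duplicate_read_not_counted(self, write_sam, toy_panel):
        dup = sam_line("r2", pos=10000, seq="G" + "A" * 19, flag=0x400)
        path, _ = write_sam(sam_line("r1", pos=10000, seq="A" * 20), dup)
        c = _by_pos(count_alleles(path, toy_panel))[("1", 10000)]
        assert (c.n_maternal, c.n_nonmaternal) == (1, 0)
        relaxed = CountFilters(exclude_duplicates=False)
        c2 = _by_pos(count_alleles(path, toy_panel, relaxed))[("1", 10000)]
        assert (c2.n_maternal, c2.n_nonmaternal) == (1, 1)

    def test_overlapping_mates_count_once(self, write_sam, toy_panel):
        # both mates of one template cover chr1:10000; higher-quality base wins
        r1 = sam_line("tpl", pos=9990, seq="A" * 11 + "G" + "A" * 8,
                      flag=0x63, qual="I" * 10 + "5" + "I" * 9)  # G at Q20
        r2 = sam_line("tpl", pos=10000, seq="A" * 20, flag=0x93)  # A at Q40
        path, _ = write_sam(r1, r2)
        c = _by_pos(count_alleles(path, toy_panel))[("1", 10000)]
        assert (c.n_maternal, c.n_nonmaternal) == (1, 0)

    def test_deletion_over_locus_discarded(self, write_sam, toy_panel):
        path, _ = write_sam(
            sam_line("r1", pos=9995, seq="A" * 15, cigar="5M5D10M",
                     qual="I" * 15)
        )
        c = _by_pos(count_alleles(path, toy_panel))[("1", 10000)]
        assert c.depth == 0 and c.n_discarded == 1

    def test_no_overlap_is_error(self, write_sam, toy_panel):
        path, _ = write_sam(sam_line("r1", pos=50000, seq="A" * 20))
        with pytest.raises(ValueError, match="no alignments overlap"):
            count_alleles(path, toy_panel)

    def test_order_independence(self, write_sam, toy_panel, tmp_path):
        lines = [
            sam_line("r1", pos=9990, seq="A" * 20),
            sam_line("r2", pos=10000, seq="G" + "A" * 19),
            sam_line("r3", chrom="chr2", pos=495, seq="G" * 10),
            sam_line("r4", pos=10040, seq="C" * 20),
        ]
        path, _ = write_sam(*lines)
        ref = {
            k: (c.n_maternal, c.n_nonmaternal, c.n_discarded)
            for k, c in _by_pos(count_alleles(path, toy_panel)).items()
        }
        rng = random.Random(0)
        for _ in range(3):
            rng.shuffle(lines)
            shuffled = tmp_path / "shuffled.sam"
            shuffled.write_text(SAM_HEADER + "".join(lines))
            got = {
                k: (c.n_maternal, c.n_nonmaternal, c.n_discarded)
                for k, c in _by_pos(count_alleles(shuffled, toy_panel)).items()
            }
            assert got == ref

    def test_agreement_with_bruteforce_oracle(self, write_sam, toy_panel):
        # 50 random reads, random bases/qualities/flags over all three loci
        rng = random.Random(42)
        lines = []
        for i in range(50):
            chrom = rng.choice(["chr1", "chr1", "chr2"])
            pos = rng.choice([9985, 9995, 10000, 10035, 10045, 490, 495])
            seq = "".join(rng.choice("ACGTN") for _ in range(20))
            qual = "".join(chr(33 + rng.choice([2, 15, 20, 30, 40])) for _ in range(20))
            flag = rng.choice([0, 0, 0, 0x400])
            mapq = rng.choice([0, 60, 60])
            lines.append(
                sam_line(f"r{i}", chrom=chrom, pos=pos, seq=seq, flag=flag,
                         mapq=mapq, qual=qual)
            )
        path, text = write_sam(*lines)
        sites = {
            (e.locus.chrom, e.locus.pos): e.maternal_allele for e in toy_panel
        }
        expected = oracle_counts(text, sites)
        got = _by_pos(count_alleles(path, toy_panel))
        assert set(got) == set(expected)
        for key, (n_mat, n_non, n_disc) in expected.items():
            c = got[key]
            assert (c.n_maternal, c.n_nonmaternal, c.n_discarded) == (
                n_mat, n_non, n_disc
            ), key

    def test_empty_panel_rejected(self, write_sam):
        path, _ = write_sam(sam_line("r1"))
        with pytest.raises(ValueError, match="empty panel"):
            count_alleles(path, HomozygousPanel([]))


def _counts(maternal="A", pos=100, chrom="1", **bases):
    ref, alt = (maternal, "G") if maternal != "G" else ("G", "A")
    rec = LocusAlleleCounts(SnpLocus(chrom, pos, ref, alt), maternal)
    rec.base_counts = {k[-1]: v for k, v in bases.items()}
    return rec


class TestSummarize:
    def test_percentage_arithmetic(self):
        # 10,000 bases of which 35 non-maternal -> X = 0.35%
        recs = [
            _counts(pos=1, n_A=5000, n_G=20),
            _counts(pos=2, n_A=4965, n_T=15),
        ]
        s = summarize_nonmaternal(recs)
        assert s.total_bases == 10000 and s.nonmaternal_bases == 35
        assert s.x_pct == pytest.approx(0.35)
        assert s.n_loci_covered == 2

    def test_all_maternal_gives_zero(self):
        s = summarize_nonmaternal([_counts(pos=1, n_A=100)])
        assert s.x_pct == 0.0

    def test_zero_total_is_error(self):
        with pytest.raises(ValueError):
            summarize_nonmaternal([])

    def test_invariant_under_chrom_renaming_and_order(self):
        a = [_counts(pos=1, chrom="chr1", n_A=90, n_G=10),
             _counts(pos=2, chrom="chr2", n_A=50)]
        b = [_counts(pos=2, chrom="2", n_A=50),
             _counts(pos=1, chrom="1", n_A=90, n_G=10)]
        assert summarize_nonmaternal(a).x_pct == summarize_nonmaternal(b).x_pct


class TestActualFraction:
    def test_closed_form(self):
        assert ActualFractionResult(10, 90).f_pct == pytest.approx(20.0)
        assert ActualFractionResult(0, 500).f_pct == 0.0

    def test_zero_informative_is_error(self):
        with pytest.raises(ZeroDivisionError):
            ActualFractionResult(0, 0).f_pct

    def test_restricts_to_fetal_het_sites(self):
        counts = [
            _counts(pos=1, n_A=90, n_G=10),  # fetal AB: informative
            _counts(pos=2, n_A=80, n_G=20),  # fetal AA: not informative
            _counts(pos=3, n_A=70, n_G=10, n_T=5),  # AB; T matches neither
        ]
        fetal = [
            GenotypeRecord(counts[0].locus, "AB"),
            GenotypeRecord(counts[1].locus, "AA"),
            GenotypeRecord(counts[2].locus, "AB"),
        ]
        res = compute_actual_fraction(counts, fetal)
        assert (res.p, res.q) == (20, 160)
        assert res.f_pct == pytest.approx(200 * 20 / 180)

    def test_no_informative_sites_is_error(self):
        counts = [_counts(pos=1, n_A=10)]
        with pytest.raises(ValueError):
            compute_actual_fraction(counts, [GenotypeRecord(counts[0].locus, "AA")])

    def test_half_panel_stays_within_binomial_noise(self):
        # splitting informative loci at random perturbs F only by sampling noise
        import numpy as np

        rng = np.random.default_rng(0)
        f_true = 10.0
        counts, fetal = [], []
        for i in range(2000):
            depth = 50
            p = rng.binomial(depth, f_true / 200)
            rec = _counts(pos=i + 1, n_A=depth - p, n_G=int(p))
            counts.append(rec)
            fetal.append(GenotypeRecord(rec.locus, "AB"))
        full = compute_actual_fraction(counts, fetal).f_pct
        half_idx = rng.choice(2000, 1000, replace=False)
        half = compute_actual_fraction([counts[i] for i in half_idx], fetal).f_pct
        n_half = sum(counts[i].depth for i in half_idx)
        sd = 200 * np.sqrt((f_true / 200) * (1 - f_true / 200) / n_half)
        assert abs(half - full) < 4 * sd


class TestCountsIO:
    def test_full_dialect_round_trip(self, tmp_path):
        recs = [_counts(pos=1, n_A=10, n_G=2), _counts(pos=2, maternal="C", n_C=7)]
        recs[0].n_discarded = 3
        path = tmp_path / "counts.tsv"
        write_counts(recs, path)
        back = read_counts(path)
        assert [(c.locus.pos, c.base_counts, c.n_discarded) for c in back] == [
            (1, {"A": 10, "G": 2}, 3),
            (2, {"C": 7}, 0),
        ]

    def test_minimal_pileup_dialect(self, tmp_path):
        path = tmp_path / "pileup.tsv"
        path.write_text(
            "chrom\tpos\tmaternal_allele\tn_maternal\tn_nonmaternal\n"
            "1\t100\tA\t95\t5\n"
            "1\t200\tG\t50\t0\n"
        )
        recs = read_counts(path)
        s = summarize_nonmaternal(recs)
        assert s.total_bases == 150 and s.nonmaternal_bases == 5
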