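"""Allele counting at maternal-homozygous SNP sites.

Given plasma alignments (SAM/BAM) and a maternal-homozygous panel, count at
each panel site the plasma bases that match the maternal allele versus any
other A/C/G/T base.  Aggregating the non-maternal bases genome-wide gives the
non-maternal allele fraction X (in percent), the single statistic the linear
calibration consumes.  With fetal genotypes available as well, the
gold-standard fetal fraction F = 2p/(p+q) x 100 is computed from the sites
where the mother is homozygous and the fetus heterozygous.

Filtering defaults: base quality >= 20, mapping quality >= 20; duplicate,
secondary, supplementary and unmapped records excluded; when both mates of a
pair cover a site only the higher-quality base is counted, so one template
molecule contributes at most one base per locus.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional

from .panel import (
    GenotypeRecord,
    HomozygousPanel,
    PanelEntry,
    SnpLocus,
    normalize_chrom,
)

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")


@dataclass
class CountFilters:
    """Quality thresholds applied during pileup."""

    min_base_quality: int = 20
    min_mapping_quality: int = 20
    exclude_duplicates: bool = True


@dataclass
class LocusAlleleCounts:
    """Per-locus tally of plasma bases.

    ``base_counts`` holds counted A/C/G/T bases; ``n_discarded`` counts bases
    failing quality filters, Ns, and deletions/reference skips over the site.
    """

    locus: SnpLocus
    maternal_allele: str
    base_counts: Dict[str, int] = field(default_factory=dict)
    n_discarded: int = 0

    @property
    def n_maternal(self) -> int:
        return self.base_counts.get(self.maternal_allele, 0)

    @property
    def n_nonmaternal(self) -> int:
        return sum(v for b, v in self.base_counts.items() if b != self.maternal_allele)

    @property
    def depth(self) -> int:
        return self.n_maternal + self.n_nonmaternal


@dataclass
class PlasmaAlleleSummary:
    """Genome-wide aggregate over a sample's panel sites; houses X."""

    total_bases: int
    nonmaternal_bases: int
    n_loci_covered: int

    @property
    def x_pct(self) -> float:
        """Non-maternal allele fraction, percent."""
        return 100.0 * self.nonmaternal_bases / self.total_bases

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "total_bases": self.total_bases,
                    "nonmaternal_bases": self.nonmaternal_bases,
                    "n_loci_covered": self.n_loci_covered,
                    "x_pct": self.x_pct,
                },
                fh,
                indent=2,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlasmaAlleleSummary":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["total_bases"], d["nonmaternal_bases"], d["n_loci_covered"])


@dataclass
class ActualFractionResult:
    """Gold-standard fetal fraction from known maternal+fetal genotypes.

    p = sequenced bases carrying the fetal-specific allele at sites where the
    mother is homozygous and the fetus heterozygous; q = bases carrying the
    shared (maternal) allele at those sites; F = 2p/(p+q) x 100 percent.
    """

    p: int
    q: int

    @property
    def f_pct(self) -> float:
        if self.p + self.q == 0:
            raise ZeroDivisionError("no informative bases (p + q = 0)")
        return 200.0 * self.p / (self.p + self.q)


def count_alleles(
    alignments: str | Path,
    panel: HomozygousPanel,
    filters: Optional[CountFilters] = None,
) -> list[LocusAlleleCounts]:
    """Pile up plasma alignments over the panel and tally alleles per locus.

    Streams the file sequentially (no index needed for SAM); each aligned
    segment contributes at most one base per locus, and overlapping mates of
    one pair are collapsed to the higher-quality base.  Returns one record per
    panel locus with at least one observed (counted or discarded) base.
    """
    import pysam

    filters = filters or CountFilters()
    if len(panel) == 0:
        raise ValueError("empty panel: nothing to count")

    by_chrom = panel.by_chrom()
    positions: dict[str, list[int]] = {
        c: [e.locus.pos for e in entries] for c, entries in by_chrom.items()
    }

    # per (chrom, pos): template name -> (base|None, qual); None = deletion/refskip
    observed: dict[tuple, dict[str, tuple]] = {}

    n_reads = 0
    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if filters.exclude_duplicates and read.is_duplicate:
                continue
            if read.mapping_quality < filters.min_mapping_quality:
                continue
            chrom = normalize_chrom(read.reference_name)
            pos_list = positions.get(chrom)
            if not pos_list:
                continue
            start1 = read.reference_start + 1  # 1-based inclusive
            end1 = read.reference_end  # 1-based inclusive
            lo = _bisect_left(pos_list, start1)
            hi = _bisect_right(pos_list, end1)
            if lo >= hi:
                continue
            n_reads += 1
            ref2query = {
                rpos: qpos
                for qpos, rpos in read.get_aligned_pairs()
                if rpos is not None
            }
            seq = read.query_sequence
            quals = read.query_qualities
            for pos in pos_list[lo:hi]:
                qpos = ref2query.get(pos - 1)
                if qpos is None:
                    base, qual = None, -1  # deletion or refskip over the site
                else:
                    base = seq[qpos].upper()
                    qual = quals[qpos] if quals is not None else 0
                site = observed.setdefault((chrom, pos), {})
                prev = site.get(read.query_name)
                if prev is None or qual > prev[1]:
                    site[read.query_name] = (base, qual)

    if not observed:
        raise ValueError("no alignments overlap the panel; estimation impossible")
    logger.info("counted %d reads over %d panel sites", n_reads, len(observed))

    out: list[LocusAlleleCounts] = []
    for chrom, entries in by_chrom.items():
        for e in entries:
            site = observed.get((chrom, e.locus.pos))
            if not site:
                continue
            rec = LocusAlleleCounts(e.locus, e.maternal_allele)
            for base, qual in site.values():
                if base is None or base not in _BASES or qual < filters.min_base_quality:
                    rec.n_discarded += 1
                else:
                    rec.base_counts[base] = rec.base_counts.get(base, 0) + 1
            out.append(rec)
    return out


def _bisect_left(a, x):
    import bisect

    return bisect.bisect_left(a, x)


def _bisect_right(a, x):
    import bisect

    return bisect.bisect_right(a, x)


def summarize_nonmaternal(counts: Iterable[LocusAlleleCounts]) -> PlasmaAlleleSummary:
    """Aggregate per-locus counts into the genome-wide summary with X."""
    total = 0
    nonmat = 0
    covered = 0
    for c in counts:
        d = c.depth
        total += d
        nonmat += c.n_nonmaternal
        if d > 0:
            covered += 1
    if total == 0:
        raise ValueError("zero counted bases: cannot compute X")
    return PlasmaAlleleSummary(total, nonmat, covered)


def compute_actual_fraction(
    counts: Iterable[LocusAlleleCounts],
    fetal_genotypes: Iterable[GenotypeRecord],
) -> ActualFractionResult:
    """Gold-standard F over loci where the fetus is heterozygous.

    Restricts to panel loci (maternal homozygous by construction) with fetal
    genotype AB, so the fetal-specific allele is the locus allele the mother
    does not carry.  Bases matching neither locus allele are ignored.
    """
    fetal = {
        (normalize_chrom(g.locus.chrom), g.locus.pos): g.genotype
        for g in fetal_genotypes
    }
    p = 0
    q = 0
    for c in counts:
        gt = fetal.get((normalize_chrom(c.locus.chrom), c.locus.pos))
        if gt != "AB":
            continue
        alleles = (c.locus.ref_allele, c.locus.alt_allele)
        if c.maternal_allele not in alleles:
            continue
        specific = alleles[1] if c.maternal_allele == alleles[0] else alleles[0]
        p += c.base_counts.get(specific, 0)
        q += c.base_counts.get(c.maternal_allele, 0)
    if p + q == 0:
        raise ValueError("no informative bases at maternal-hom/fetal-het sites")
    return ActualFractionResult(p, q)


_COUNTS_HEADER = [
    "chrom", "pos", "ref", "alt", "maternal_allele",
    "count_A", "count_C", "count_G", "count_T", "n_discarded",
]


def write_counts(counts: Iterable[LocusAlleleCounts], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_COUNTS_HEADER)
        for c in counts:
            w.writerow(
                [c.locus.chrom, c.locus.pos, c.locus.ref_allele, c.locus.alt_allele,
                 c.maternal_allele]
                + [c.base_counts.get(b, 0) for b in _BASES]
                + [c.n_discarded]
            )


def read_counts(path: str | Path) -> list[LocusAlleleCounts]:
    """Read per-locus counts from TSV.

    Accepts both this package's full dialect (per-base columns, see
    ``write_counts``) and the minimal pileup dialect
    ``chrom pos maternal_allele n_maternal n_nonmaternal`` in which the
    non-maternal bases are not attributed to a specific allele (they are
    booked against a locus allele distinct from the maternal one, which is
    exact for the summary statistic X).
    """
    out: list[LocusAlleleCounts] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:5] == _COUNTS_HEADER[:5]:
            for row in reader:
                locus = SnpLocus(row[0], int(row[1]), row[2], row[3])
                rec = LocusAlleleCounts(locus, row[4], n_discarded=int(row[9]))
                for b, v in zip(_BASES, row[5:9]):
                    if int(v):
                        rec.base_counts[b] = int(v)
                out.append(rec)
        elif [h.lower() for h in header[:5]] == [
            "chrom", "pos", "maternal_allele", "n_maternal", "n_nonmaternal"
        ]:
            for row in reader:
                mat = row[2].upper()
                other = "A" if mat != "A" else "C"
                locus = SnpLocus(row[0], int(row[1]), mat, other)
                rec = LocusAlleleCounts(locus, mat)
                if int(row[3]):
                    rec.base_counts[mat] = int(row[3])
                if int(row[4]):
                    rec.base_counts[other] = int(row[4])
                out.append(rec)
        else:
            raise ValueError(f"{path}: unrecognised counts header {header!r}")
    return out


def panel_entry(counts: LocusAlleleCounts) -> PanelEntry:
    return PanelEntry(counts.locus, counts.maternal_allele)
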