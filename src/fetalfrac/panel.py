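"""SNP panels and genotypes.

The estimator works from the set of SNP loci at which the mother is
homozygous: any sequenced plasma base differing from the maternal allele at
such a site is a candidate fetal (paternally inherited) allele.  This module
reads maternal (or fetal) genotypes from VCF or a simple TSV dialect, derives
the maternal-homozygous panel, and round-trips panels to disk.

Coordinates are 1-based fully-closed (VCF convention) throughout; BED export
(0-based half-open) is available via :meth:`HomozygousPanel.to_bed`.
Chromosome names are normalised by stripping a leading ``chr`` prefix so that
panels and alignments from differently-styled references match.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
GENOTYPE_CODES = ("AA", "AB", "BB", "missing")

#: autosome names after chr-prefix normalisation
AUTOSOMES = frozenset(str(c) for c in range(1, 23))


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    if name[:3].lower() == "chr":
        return name[3:]
    return name


def is_sex_chrom(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() in {"X", "Y"}


@dataclass(frozen=True)
class SnpLocus:
    """A biallelic SNP site.

    ``pop_alt_freq`` is the population alternative-allele frequency; it is
    optional and only consulted by the synthetic-data generator.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    pop_alt_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single bases in ACGT, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.pop_alt_freq is not None and not 0.0 <= self.pop_alt_freq <= 1.0:
            raise ValueError("pop_alt_freq must lie in [0, 1]")

    @property
    def key(self) -> tuple:
        """Sort/uniqueness key on normalised (chrom, pos)."""
        return (_chrom_sort_key(normalize_chrom(self.chrom)), self.pos)


def _chrom_sort_key(chrom: str) -> tuple:
    # numeric chromosomes before named ones, both in natural order
    try:
        return (0, int(chrom), "")
    except ValueError:
        return (1, 0, chrom)


@dataclass(frozen=True)
class GenotypeRecord:
    locus: SnpLocus
    genotype: str  # one of GENOTYPE_CODES; A = ref, B = alt

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPE_CODES:
            raise ValueError(f"genotype must be one of {GENOTYPE_CODES}")


@dataclass(frozen=True)
class PanelEntry:
    locus: SnpLocus
    maternal_allele: str

    def __post_init__(self) -> None:
        if self.maternal_allele not in (self.locus.ref_allele, self.locus.alt_allele):
            raise ValueError("maternal allele must be the locus ref or alt allele")


class HomozygousPanel:
    """Ordered, duplicate-free collection of maternal-homozygous SNP sites.

    Entries are kept sorted by normalised (chrom, pos) and unique by that key;
    construction enforces both.
    """

    def __init__(self, entries: Iterable[PanelEntry]) -> None:
        seen: dict[tuple, PanelEntry] = {}
        for e in entries:
            k = e.locus.key
            if k in seen:
                raise ValueError(
                    f"duplicate panel locus {e.locus.chrom}:{e.locus.pos}"
                )
            seen[k] = e
        self._entries: list[PanelEntry] = [seen[k] for k in sorted(seen)]

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self._entries)

    def __getitem__(self, i: int) -> PanelEntry:
        return self._entries[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HomozygousPanel):
            return NotImplemented
        return self._entries == other._entries

    def by_chrom(self) -> dict[str, list[PanelEntry]]:
        """Entries grouped by normalised chromosome name, position-sorted."""
        out: dict[str, list[PanelEntry]] = {}
        for e in self._entries:
            out.setdefault(normalize_chrom(e.locus.chrom), []).append(e)
        return out

    def to_bed(self, path: str | Path) -> None:
        """Export locus coordinates as BED (0-based half-open)."""
        with open(path, "w") as fh:
            for e in self._entries:
                fh.write(
                    f"{e.locus.chrom}\t{e.locus.pos - 1}\t{e.locus.pos}\t"
                    f"{e.locus.ref_allele}/{e.locus.alt_allele}\n"
                )


class GenotypeSet(list):
    """List of :class:`GenotypeRecord` that remembers how many input records
    were skipped (multi-allelic, indel, malformed)."""

    def __init__(self, records: Iterable[GenotypeRecord] = (), n_skipped: int = 0):
        super().__init__(records)
        self.n_skipped = n_skipped


def read_genotypes(path: str | Path, format: Optional[str] = None) -> GenotypeSet:
    """Read single-sample genotypes from a VCF or TSV file.

    The TSV dialect is ``chrom  pos  ref  alt  genotype  [alt_freq]`` with an
    optional header line; genotype is one of AA/AB/BB (A = ref, B = alt) or
    ``./.``/``NN``/``missing``.  Multi-allelic and indel records are skipped
    and counted on the returned set's ``n_skipped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_vcf(path: Path) -> GenotypeSet:
    from cyvcf2 import VCF

    records: list[GenotypeRecord] = []
    n_skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.REF not in VALID_BASES or var.ALT[0] not in VALID_BASES:
            n_skipped += 1
            continue
        locus = SnpLocus(var.CHROM, var.POS, var.REF, var.ALT[0])
        a, b = var.genotypes[0][0], var.genotypes[0][1]
        if a < 0 or b < 0:
            gt = "missing"
        elif a == 0 and b == 0:
            gt = "AA"
        elif a == 1 and b == 1:
            gt = "BB"
        else:
            gt = "AB"
        records.append(GenotypeRecord(locus, gt))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic/indel VCF records", n_skipped)
    return GenotypeSet(records, n_skipped)


_TSV_GT = {
    "AA": "AA", "AB": "AB", "BA": "AB", "BB": "BB",
    "./.": "missing", "NN": "missing", "missing": "missing",
}


def _read_genotypes_tsv(path: Path) -> GenotypeSet:
    records: list[GenotypeRecord] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() in {"chrom", "chr", "chromosome"}:
                continue  # header
            try:
                chrom, pos, ref, alt, gt = fields[:5]
                freq = float(fields[5]) if len(fields) > 5 and fields[5] else None
                if len(ref) != 1 or len(alt) != 1:
                    raise ValueError("indel")
                locus = SnpLocus(chrom, int(pos), ref.upper(), alt.upper(), freq)
                records.append(GenotypeRecord(locus, _TSV_GT[gt.upper() if gt not in _TSV_GT else gt]))
            except (ValueError, KeyError, IndexError) as exc:
                logger.warning("skipping malformed line %d of %s: %s", lineno, path, exc)
                n_skipped += 1
    return GenotypeSet(records, n_skipped)


def select_homozygous(
    genotypes: Iterable[GenotypeRecord], include_sex: bool = False
) -> HomozygousPanel:
    """Build the maternal-homozygous panel from a genotype set.

    Keeps AA and BB records (maternal allele = ref resp. alt); heterozygous
    and missing genotypes are dropped.  Sex chromosomes are excluded unless
    ``include_sex`` is set — chrY reads from a male fetus would otherwise
    masquerade as non-maternal signal.
    """
    entries = []
    for rec in genotypes:
        if rec.genotype not in ("AA", "BB"):
            continue
        if not include_sex and is_sex_chrom(rec.locus.chrom):
            continue
        allele = rec.locus.ref_allele if rec.genotype == "AA" else rec.locus.alt_allele
        entries.append(PanelEntry(rec.locus, allele))
    panel = HomozygousPanel(entries)
    if len(panel) == 0:
        logger.warning("no homozygous loci found; downstream estimation will fail")
    return panel


def panel_to_genotypes(panel: HomozygousPanel) -> GenotypeSet:
    """Recast a panel as genotype records (AA for maternal=ref, BB for alt)."""
    recs = [
        GenotypeRecord(e.locus, "AA" if e.maternal_allele == e.locus.ref_allele else "BB")
        for e in panel
    ]
    return GenotypeSet(recs, 0)


_PANEL_HEADER = ["chrom", "pos", "ref", "alt", "maternal_allele", "alt_freq"]


def write_panel(panel: HomozygousPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PANEL_HEADER)
        for e in panel:
            w.writerow(
                [
                    e.locus.chrom,
                    e.locus.pos,
                    e.locus.ref_allele,
                    e.locus.alt_allele,
                    e.maternal_allele,
                    "" if e.locus.pop_alt_freq is None else repr(e.locus.pop_alt_freq),
                ]
            )


def read_panel(path: str | Path) -> HomozygousPanel:
    entries = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return HomozygousPanel([])
        if header[0] != "chrom":
            raise ValueError(f"{path}: not a panel file (missing header)")
        for row in reader:
            chrom, pos, ref, alt, mat = row[:5]
            freq = float(row[5]) if len(row) > 5 and row[5] else None
            entries.append(PanelEntry(SnpLocus(chrom, int(pos), ref, alt, freq), mat))
    return HomozygousPanel(entries)
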