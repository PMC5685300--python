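"""Synthetic maternal-plasma data with the statistical structure the
estimator assumes.

The generative model is the linear relationship underlying the calibration:
at a maternal-homozygous site, a plasma base is non-maternal either because
it comes from a fetal-specific allele (the site is "informative": the fetus
is heterozygous for an allele the mother does not carry, which happens with
probability ``pi_informative`` per panel locus, and then half the fetal-
derived bases carry it) or because of a constant sequencing/genotyping error
(``epsilon_pct`` percent of bases, uniform across loci).  Hence

    E[X] = pi_informative * f / 2 + epsilon_pct        (percent scale)

with f the true fetal fraction in percent, so the implied calibration line is
F_hat = (2/pi) * X - (2/pi) * epsilon.  The default pi = 0.10582 and
epsilon = 0.34921% make that implied line coincide with the shipped published
calibration (slope 18.9, intercept -6.6); they are algebraic back-derivations,
not measured quantities.

Three modes:

``aggregate``   scalar genome-wide counts only (fast; any panel size);
``site_level``  per-locus allele counts plus fetal genotypes, flowing through
                the same code paths as real pileup data;
``sam_emit``    a small SAM + maternal/fetal VCF realisation of a site-level
                draw, for end-to-end I/O tests.

Coverage converts to read pairs via a 3.1 Gb genome and 100 bp per pair
(2 x 50 bp), so 1 million pairs is about 0.032-fold coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .counting import (
    ActualFractionResult,
    LocusAlleleCounts,
    PlasmaAlleleSummary,
    compute_actual_fraction,
    summarize_nonmaternal,
)
from .panel import GenotypeRecord, HomozygousPanel, PanelEntry, SnpLocus

GENOME_LENGTH = 3.1e9
READ_PAIR_BASES = 100  # 2 x 50 bp

#: default panel size — homozygous loci retained from a 2.35M-SNP array
DEFAULT_N_LOCI = 1_940_000
#: probability a panel locus is fetal-informative (maternal hom, fetal het)
DEFAULT_PI_INFORMATIVE = 0.10582
#: baseline non-maternal error rate, percent of bases
DEFAULT_EPSILON_PCT = 0.34921
#: full-study depth: ~139.5M pairs x 100 bp / 3.1 Gb
DEFAULT_COVERAGE = 4.5

_MODES = ("aggregate", "site_level", "sam_emit")


def coverage_from_pairs(n_pairs: float) -> float:
    """Fold-coverage achieved by ``n_pairs`` read pairs of 2 x 50 bp."""
    return n_pairs * READ_PAIR_BASES / GENOME_LENGTH


def pairs_from_coverage(coverage: float) -> float:
    return coverage * GENOME_LENGTH / READ_PAIR_BASES


@dataclass
class SimulationConfig:
    n_loci: int = DEFAULT_N_LOCI
    pi_informative: float = DEFAULT_PI_INFORMATIVE
    epsilon_pct: float = DEFAULT_EPSILON_PCT
    coverage: float = DEFAULT_COVERAGE
    f_true_pct: float = 10.0
    seed: Optional[int] = None
    mode: str = "aggregate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi_informative <= 1.0:
            raise ValueError("pi_informative must lie in [0, 1]")
        if self.epsilon_pct < 0:
            raise ValueError("epsilon_pct must be >= 0")
        if not 0.0 <= self.f_true_pct <= 100.0:
            raise ValueError("f_true_pct must lie in [0, 100]")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.nonmaternal_rate > 1.0:
            raise ValueError("pi*f/200 + epsilon/100 exceeds 1: invalid config")

    @property
    def nonmaternal_rate(self) -> float:
        """Per-base probability of observing a non-maternal allele."""
        return (
            self.pi_informative * self.f_true_pct / 200.0
            + self.epsilon_pct / 100.0
        )

    @property
    def expected_x_pct(self) -> float:
        """Closed-form E[X] = pi*f/2 + epsilon, percent."""
        return 100.0 * self.nonmaternal_rate


@dataclass
class SimulatedSample:
    """One synthetic plasma sample.

    In aggregate mode only the scalar totals are populated; in site-level
    mode ``counts`` and ``fetal_genotypes`` additionally hold the per-locus
    realisation and the aggregate fields are derived from it.
    """

    sample_id: str
    f_true_pct: float
    n_loci: int
    coverage: float
    mode: str
    total_bases: int
    nonmaternal_bases: int
    informative_bases: int
    fetal_specific_bases: int
    counts: Optional[list[LocusAlleleCounts]] = None
    fetal_genotypes: Optional[list[GenotypeRecord]] = None
    panel: Optional[HomozygousPanel] = None

    @property
    def x_pct(self) -> float:
        if self.total_bases == 0:
            raise ZeroDivisionError("sample has no counted bases")
        return 100.0 * self.nonmaternal_bases / self.total_bases

    @property
    def n_pairs(self) -> float:
        """Read pairs the sample's coverage corresponds to (genome-wide)."""
        return pairs_from_coverage(self.coverage)

    def summary(self) -> PlasmaAlleleSummary:
        if self.counts is not None:
            return summarize_nonmaternal(self.counts)
        # fraction of loci hit by >=1 base under Poisson(coverage) depth
        covered = int(round(self.n_loci * (1.0 - math.exp(-self.coverage))))
        return PlasmaAlleleSummary(self.total_bases, self.nonmaternal_bases, covered)

    def actual_fraction(self) -> ActualFractionResult:
        """Gold-standard F from the informative-site realisation."""
        if self.counts is not None and self.fetal_genotypes is not None:
            return compute_actual_fraction(self.counts, self.fetal_genotypes)
        q = self.informative_bases - self.fetal_specific_bases
        return ActualFractionResult(self.fetal_specific_bases, q)


def simulate_sample(
    config: SimulationConfig,
    sample_id: str = "sim",
    rng: Optional[np.random.Generator] = None,
    out_dir: Optional[str | Path] = None,
) -> SimulatedSample:
    """Draw one synthetic sample under ``config``.

    ``out_dir`` is required (and only used) in ``sam_emit`` mode, where the
    SAM and VCF files are written under it.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.mode == "aggregate":
        return _simulate_aggregate(config, sample_id, rng)
    sample = _simulate_site_level(config, sample_id, rng)
    if config.mode == "sam_emit":
        if out_dir is None:
            raise ValueError("sam_emit mode requires out_dir")
        emit_sam(sample, out_dir)
    return sample


def _simulate_aggregate(
    config: SimulationConfig, sample_id: str, rng: np.random.Generator
) -> SimulatedSample:
    n_total = int(rng.poisson(config.n_loci * config.coverage))
    nonmat = int(rng.binomial(n_total, config.nonmaternal_rate)) if n_total else 0
    n_inf = int(rng.binomial(n_total, config.pi_informative)) if n_total else 0
    p = int(rng.binomial(n_inf, config.f_true_pct / 200.0)) if n_inf else 0
    return SimulatedSample(
        sample_id=sample_id,
        f_true_pct=config.f_true_pct,
        n_loci=config.n_loci,
        coverage=config.coverage,
        mode="aggregate",
        total_bases=n_total,
        nonmaternal_bases=nonmat,
        informative_bases=n_inf,
        fetal_specific_bases=p,
    )


_LOCUS_SPACING = 200  # bp between simulated loci; a 50 bp read spans one locus


def _simulate_site_level(
    config: SimulationConfig, sample_id: str, rng: np.random.Generator
) -> SimulatedSample:
    n = config.n_loci
    pos = 101 + _LOCUS_SPACING * np.arange(n, dtype=np.int64)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    maternal_is_ref = rng.random(n) < 0.5

    depth = rng.poisson(config.coverage, size=n)
    informative = rng.random(n) < config.pi_informative
    fetal_rate = np.where(informative, config.f_true_pct / 200.0, 0.0)
    fetal_b = rng.binomial(depth, fetal_rate)
    err = rng.binomial(depth - fetal_b, config.epsilon_pct / 100.0)
    # split errors uniformly over the three non-maternal bases
    e1 = rng.binomial(err, 1.0 / 3.0)
    e2 = rng.binomial(err - e1, 0.5)
    e3 = err - e1 - e2

    entries: list[PanelEntry] = []
    counts: list[LocusAlleleCounts] = []
    fetal_gts: list[GenotypeRecord] = []
    for i in range(n):
        ref, alt = bases[ref_idx[i]], bases[alt_idx[i]]
        locus = SnpLocus("1", int(pos[i]), ref, alt)
        maternal = ref if maternal_is_ref[i] else alt
        other = alt if maternal_is_ref[i] else ref
        entries.append(PanelEntry(locus, maternal))
        maternal_gt = "AA" if maternal_is_ref[i] else "BB"
        fetal_gts.append(GenotypeRecord(locus, "AB" if informative[i] else maternal_gt))
        if depth[i] == 0:
            continue
        rec = LocusAlleleCounts(locus, maternal)
        err_targets = sorted(set("ACGT") - {maternal})
        for b, c in zip(err_targets, (int(e1[i]), int(e2[i]), int(e3[i]))):
            if c:
                rec.base_counts[b] = rec.base_counts.get(b, 0) + c
        if fetal_b[i]:
            rec.base_counts[other] = rec.base_counts.get(other, 0) + int(fetal_b[i])
        n_mat = int(depth[i] - fetal_b[i] - err[i])
        if n_mat:
            rec.base_counts[maternal] = rec.base_counts.get(maternal, 0) + n_mat
        counts.append(rec)

    panel = HomozygousPanel(entries)
    summ = summarize_nonmaternal(counts) if counts else None
    inf_mask = informative & (depth > 0)
    sample = SimulatedSample(
        sample_id=sample_id,
        f_true_pct=config.f_true_pct,
        n_loci=n,
        coverage=config.coverage,
        mode=config.mode,
        total_bases=summ.total_bases if summ else 0,
        nonmaternal_bases=summ.nonmaternal_bases if summ else 0,
        informative_bases=int(depth[inf_mask].sum()),
        fetal_specific_bases=int(fetal_b.sum()),
        counts=counts,
        fetal_genotypes=fetal_gts,
        panel=panel,
    )
    return sample


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    n_samples: int,
    f_distribution: Union[str, Sequence[float]] = "clearance_study",
    config_base: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> list[SimulatedSample]:
    """Draw a cohort of samples with per-sample true fractions.

    ``f_distribution`` is either an explicit per-sample list of true
    fractions (percent) or the named preset ``"clearance_study"``, which
    mimics a pre-/post-delivery clearance cohort: ceil(n/6) samples with
    f ~ Uniform(8, 30)% (pregnant, predelivery) and the remainder with
    f ~ Uniform(0, 3)% (postdelivery, fetal DNA largely cleared).  Per-sample
    RNG streams are spawned deterministically from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    config_base = config_base or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    frac_rng = np.random.default_rng(ss.spawn(1)[0])

    if isinstance(f_distribution, str):
        if f_distribution != "clearance_study":
            raise ValueError(f"unknown fraction preset {f_distribution!r}")
        n_high = math.ceil(n_samples / 6)
        fractions = np.concatenate(
            [
                frac_rng.uniform(8.0, 30.0, size=n_high),
                frac_rng.uniform(0.0, 3.0, size=n_samples - n_high),
            ]
        )
    else:
        fractions = np.asarray(list(f_distribution), dtype=float)
        if fractions.size != n_samples:
            raise ValueError("explicit fraction list length must equal n_samples")

    child_seeds = ss.spawn(n_samples + 1)[1:]
    cohort = []
    width = max(2, len(str(n_samples - 1)))
    for i, (f, child) in enumerate(zip(fractions, child_seeds)):
        cfg = replace(config_base, f_true_pct=float(f), seed=None)
        cohort.append(
            simulate_sample(cfg, sample_id=f"S{i:0{width}d}", rng=np.random.default_rng(child))
        )
    return cohort


def cohort_to_dataframe(cohort: Iterable[SimulatedSample]):
    """Tabulate a cohort: ids, true/gold-standard fractions, X and totals."""
    import pandas as pd

    rows = []
    for s in cohort:
        rows.append(
            {
                "sample_id": s.sample_id,
                "f_true_pct": s.f_true_pct,
                "x_pct": s.x_pct,
                "f_actual_pct": s.actual_fraction().f_pct,
                "total_bases": s.total_bases,
                "nonmaternal_bases": s.nonmaternal_bases,
                "informative_bases": s.informative_bases,
                "fetal_specific_bases": s.fetal_specific_bases,
                "coverage": s.coverage,
                "n_loci": s.n_loci,
            }
        )
    return pd.DataFrame(rows)


def cohort_from_dataframe(df) -> list[SimulatedSample]:
    """Rebuild aggregate samples from a :func:`cohort_to_dataframe` table."""
    return [
        SimulatedSample(
            sample_id=str(r.sample_id),
            f_true_pct=float(r.f_true_pct),
            n_loci=int(r.n_loci),
            coverage=float(r.coverage),
            mode="aggregate",
            total_bases=int(r.total_bases),
            nonmaternal_bases=int(r.nonmaternal_bases),
            informative_bases=int(r.informative_bases),
            fetal_specific_bases=int(r.fetal_specific_bases),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# sam_emit


def emit_sam(sample: SimulatedSample, out_dir: str | Path) -> dict[str, Path]:
    """Write a SAM + maternal/fetal VCF realisation of a site-level sample.

    Each counted base becomes one unpaired 50 bp read (constant filler around
    the locus base); loci are spaced so no read spans two panel sites.
    Returns the paths written.
    """
    if sample.counts is None or sample.panel is None:
        raise ValueError("sam_emit requires a site-level sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sam_path = out_dir / f"{sample.sample_id}.sam"
    maternal_vcf = out_dir / f"{sample.sample_id}.maternal.vcf"
    fetal_vcf = out_dir / f"{sample.sample_id}.fetal.vcf"

    max_pos = max(e.locus.pos for e in sample.panel)
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:1\tLN:{max_pos + 100}\n")
        rid = 0
        for rec in sample.counts:
            start = rec.locus.pos - 25  # 1-based; locus at read offset 25 (0-based)
            for base in sorted(rec.base_counts):
                for _ in range(rec.base_counts[base]):
                    seq = "A" * 25 + base + "A" * 24
                    fh.write(
                        f"r{rid:06d}\t0\t1\t{start}\t60\t50M\t*\t0\t0\t{seq}\t{'I' * 50}\n"
                    )
                    rid += 1

    from .panel import panel_to_genotypes

    _write_vcf(panel_to_genotypes(sample.panel), maternal_vcf, "MOTHER")
    _write_vcf(sample.fetal_genotypes or [], fetal_vcf, "FETUS")
    return {"sam": sam_path, "maternal_vcf": maternal_vcf, "fetal_vcf": fetal_vcf}


_VCF_GT = {"AA": "0/0", "AB": "0/1", "BB": "1/1", "missing": "./."}


def _write_vcf(records: Iterable[GenotypeRecord], path: Path, sample_name: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}\n")
        for g in records:
            fh.write(
                f"{g.locus.chrom}\t{g.locus.pos}\t.\t{g.locus.ref_allele}\t"
                f"{g.locus.alt_allele}\t.\tPASS\t.\tGT\t{_VCF_GT[g.genotype]}\n"
            )
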