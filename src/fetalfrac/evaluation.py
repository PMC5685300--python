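"""Accuracy evaluation: deviation statistics, k-fold cross-validation,
read/SNP downsampling and the depth x panel-size accuracy grid.

Deviations are signed errors F_hat - F_actual in percent.  "95% confidence
interval" throughout means the empirical 2.5th/97.5th percentiles of the
deviation distribution (linear interpolation between order statistics): a
distribution-free description of the spread, with no normality assumption.

Read downsampling operates on read templates where per-read data exists; on
aggregate counts it is binomial thinning with keep probability
n_target / n_available, which is statistically equivalent for independently
sampled bases.  SNP downsampling is a uniform without-replacement locus
subset on panels and site-level data; on aggregate counts it is thinning by
n_snps / n_loci.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace as dc_replace
from typing import Iterable, Optional, Sequence, Tuple, Union

import numpy as np

from .counting import LocusAlleleCounts
from .model import (
    CalibrationResults,
    NegativePredictionWarning,
    TrainingSample,
    fit_model,
)
from .panel import HomozygousPanel
from .simulate import SimulatedSample

logger = logging.getLogger(__name__)

MIN_N_FOR_CI = 20


@dataclass
class DeviationStats:
    """Summary of signed deviations F_hat - F_actual (percent)."""

    deviations: np.ndarray
    median_abs_dev: float
    mean_abs_dev: float
    ci_low: float
    ci_high: float

    @property
    def ci_half_width(self) -> float:
        return (self.ci_high - self.ci_low) / 2.0


def deviation_stats(
    pairs: Union[Iterable[Tuple[float, float]], np.ndarray],
    deviations: Optional[Sequence[float]] = None,
) -> DeviationStats:
    """Deviation summary from (F_hat, F_actual) pairs.

    Pass ``deviations=`` to summarise precomputed signed deviations instead.
    The empirical 95% interval needs a few dozen points to be meaningful; a
    warning is emitted below 20.
    """
    if deviations is not None:
        dev = np.asarray(deviations, dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.size == 0:
            raise ValueError("no (F_hat, F_actual) pairs given")
        dev = arr[:, 0] - arr[:, 1]
    if dev.size == 0:
        raise ValueError("no deviations given")
    if dev.size < MIN_N_FOR_CI:
        warnings.warn(
            f"only {dev.size} deviations: the empirical 95% CI is unreliable",
            UserWarning,
            stacklevel=2,
        )
    lo, hi = np.percentile(dev, [2.5, 97.5])  # linear interpolation
    return DeviationStats(
        deviations=dev,
        median_abs_dev=float(np.median(np.abs(dev))),
        mean_abs_dev=float(np.mean(np.abs(dev))),
        ci_low=float(lo),
        ci_high=float(hi),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class FoldResult:
    fold_index: int
    slope: float
    intercept: float
    r2: float  # validation-fold prediction R^2
    stats: DeviationStats
    n_val: int


@dataclass
class CvResult:
    k: int
    folds: list[FoldResult]
    pooled: DeviationStats  # held-out deviations pooled across folds

    @property
    def mean_slope(self) -> float:
        return float(np.mean([f.slope for f in self.folds]))

    @property
    def mean_intercept(self) -> float:
        return float(np.mean([f.intercept for f in self.folds]))

    @property
    def mean_r2(self) -> float:
        return float(np.nanmean([f.r2 for f in self.folds]))

    @property
    def mean_abs_dev(self) -> float:
        return self.pooled.mean_abs_dev


def make_folds(n: int, k: int, seed: Optional[int] = None) -> list[np.ndarray]:
    """Seeded shuffle then contiguous chunking into k near-equal folds.

    When k divides n every fold has n/k samples; otherwise the first n mod k
    folds take one extra sample each.  Folds partition range(n).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    folds = []
    start = 0
    for s in sizes:
        folds.append(np.sort(order[start : start + s]))
        start += s
    return folds


def kfold_cross_validate(
    samples: Sequence[TrainingSample], k: int = 5, seed: Optional[int] = None
) -> CvResult:
    """k-fold cross-validation of the linear calibration.

    Each fold is held out once; the model is fitted on the remaining folds
    and evaluated on the held-out samples.  The per-fold R^2 is the
    prediction R^2 on the validation fold, 1 - SS_res/SS_tot (undefined for
    singleton folds, reported as NaN).  Deviations are pooled across folds
    for the overall spread.
    """
    samples = list(samples)
    folds = make_folds(len(samples), k, seed)
    x = np.array([s.x_pct for s in samples])
    f = np.array([s.f_actual_pct for s in samples])

    fold_results = []
    pooled_dev: list[np.ndarray] = []
    for i, val_idx in enumerate(folds):
        mask = np.zeros(len(samples), dtype=bool)
        mask[val_idx] = True
        res = fit_model([s for s, held in zip(samples, mask) if not held])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", NegativePredictionWarning)
            f_hat = np.atleast_1d(res.predict(x[mask]))
        dev = f_hat - f[mask]
        pooled_dev.append(dev)
        if val_idx.size < 2 or np.ptp(f[mask]) == 0:
            r2 = float("nan")
            logger.warning("fold %d too small for a validation R^2", i)
        else:
            ss_res = float(np.sum(dev**2))
            ss_tot = float(np.sum((f[mask] - f[mask].mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            stats = deviation_stats(None, deviations=dev)
        fold_results.append(
            FoldResult(i, res.slope, res.intercept, r2, stats, int(val_idx.size))
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pooled = deviation_stats(None, deviations=np.concatenate(pooled_dev))
    return CvResult(k=k, folds=fold_results, pooled=pooled)


# ---------------------------------------------------------------------------
# downsampling


def _thin_count(rng: np.random.Generator, n: int, keep: float) -> int:
    return int(rng.binomial(n, keep)) if n > 0 else 0


def _thin_locus_counts(
    counts: Iterable[LocusAlleleCounts], keep: float, rng: np.random.Generator
) -> list[LocusAlleleCounts]:
    out = []
    for c in counts:
        rec = LocusAlleleCounts(
            c.locus, c.maternal_allele, n_discarded=_thin_count(rng, c.n_discarded, keep)
        )
        for b, v in c.base_counts.items():
            t = _thin_count(rng, v, keep)
            if t:
                rec.base_counts[b] = t
        if rec.depth > 0 or rec.n_discarded > 0:
            out.append(rec)
    return out


def _thinned_sample(
    sample: SimulatedSample, keep: float, rng: np.random.Generator,
    n_loci: Optional[int] = None,
) -> SimulatedSample:
    """Binomially thin an aggregate sample's counts by ``keep``."""
    mat = sample.total_bases - sample.nonmaternal_bases
    q = sample.informative_bases - sample.fetal_specific_bases
    nonmat = _thin_count(rng, sample.nonmaternal_bases, keep)
    mat_t = _thin_count(rng, mat, keep)
    p = _thin_count(rng, sample.fetal_specific_bases, keep)
    q_t = _thin_count(rng, q, keep)
    return dc_replace(
        sample,
        total_bases=mat_t + nonmat,
        nonmaternal_bases=nonmat,
        informative_bases=p + q_t,
        fetal_specific_bases=p,
        coverage=sample.coverage * keep if n_loci is None else sample.coverage,
        n_loci=sample.n_loci if n_loci is None else n_loci,
        counts=None,
        fetal_genotypes=None,
        panel=None,
    )


def downsample_reads(
    source: Union[SimulatedSample, list],
    n_pairs: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    n_pairs_available: Optional[float] = None,
) -> Union[SimulatedSample, list]:
    """Downsample to ``n_pairs`` read pairs.

    For aggregate :class:`SimulatedSample` objects the available pairs follow
    from the sample's coverage and thinning is binomial.  For a list of
    per-locus counts, ``n_pairs_available`` must be supplied and each count is
    thinned independently.  ``n_pairs`` equal to the available count is the
    identity.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(source, SimulatedSample):
        avail = source.n_pairs
        if n_pairs > avail * (1 + 1e-9):
            raise ValueError(f"target {n_pairs:g} pairs exceeds available {avail:g}")
        keep = n_pairs / avail
        if keep >= 1.0 - 1e-12:
            return source
        if source.counts is not None:
            thinned = _thin_locus_counts(source.counts, keep, rng)
            return _rebuild_site_sample(source, thinned, coverage=source.coverage * keep)
        return _thinned_sample(source, keep, rng)
    if n_pairs_available is None:
        raise ValueError("n_pairs_available required when thinning raw counts")
    if n_pairs > n_pairs_available:
        raise ValueError("target exceeds available read pairs")
    return _thin_locus_counts(source, n_pairs / n_pairs_available, rng)


def _rebuild_site_sample(
    sample: SimulatedSample, counts: list[LocusAlleleCounts], coverage: float,
    panel: Optional[HomozygousPanel] = None,
    n_loci: Optional[int] = None,
) -> SimulatedSample:
    from .counting import compute_actual_fraction, summarize_nonmaternal

    panel = panel if panel is not None else sample.panel
    total = nonmat = 0
    if counts:
        summ = summarize_nonmaternal(counts)
        total, nonmat = summ.total_bases, summ.nonmaternal_bases
    p = q = 0
    if counts and sample.fetal_genotypes is not None:
        try:
            af = compute_actual_fraction(counts, sample.fetal_genotypes)
            p, q = af.p, af.q
        except ValueError:
            pass
    return dc_replace(
        sample,
        total_bases=total,
        nonmaternal_bases=nonmat,
        informative_bases=p + q,
        fetal_specific_bases=p,
        coverage=coverage,
        n_loci=n_loci if n_loci is not None else sample.n_loci,
        counts=counts,
        panel=panel,
    )


def downsample_snps(
    source: Union[HomozygousPanel, SimulatedSample, list],
    n_snps: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Union[HomozygousPanel, SimulatedSample, list]:
    """Restrict to a uniform random subset of ``n_snps`` panel loci.

    Panels, count lists and site-level samples get a true without-replacement
    subset; aggregate samples (no per-locus identity) are binomially thinned
    by n_snps/n_loci, equivalent up to the panel-composition variance
    O(pi(1-pi)/n_snps).  ``n_snps`` equal to the current size is the identity.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(source, HomozygousPanel):
        if n_snps > len(source):
            raise ValueError(f"n_snps={n_snps} exceeds panel size {len(source)}")
        if n_snps == len(source):
            return source
        idx = rng.choice(len(source), size=n_snps, replace=False)
        return HomozygousPanel([source[i] for i in idx])
    if isinstance(source, list):
        if n_snps > len(source):
            raise ValueError("n_snps exceeds the number of counted loci")
        if n_snps == len(source):
            return source
        idx = rng.choice(len(source), size=n_snps, replace=False)
        return [source[i] for i in sorted(idx)]
    # SimulatedSample
    if n_snps > source.n_loci:
        raise ValueError(f"n_snps={n_snps} exceeds panel size {source.n_loci}")
    if n_snps == source.n_loci:
        return source
    if source.counts is not None and source.panel is not None:
        keep_idx = rng.choice(source.n_loci, size=n_snps, replace=False)
        kept_pos = {source.panel[i].locus.key for i in keep_idx}
        counts = [c for c in source.counts if c.locus.key in kept_pos]
        panel = HomozygousPanel([source.panel[i] for i in keep_idx])
        return _rebuild_site_sample(
            source, counts, coverage=source.coverage, panel=panel, n_loci=n_snps
        )
    return _thinned_sample(source, n_snps / source.n_loci, rng, n_loci=n_snps)


# ---------------------------------------------------------------------------
# accuracy grid


@dataclass
class GridCell:
    """One cell of the depth x panel-size accuracy grid."""

    n_reads: float  # read pairs
    n_snps: int
    ci_half_width: float  # percent; NaN when missing
    n_deviations: int
    missing: bool = False


def grid_evaluate(
    samples: Sequence[SimulatedSample],
    model: CalibrationResults,
    read_grid: Sequence[float],
    snp_grid: Sequence[int],
    reps: int = 20,
    seed: Optional[int] = None,
) -> list[GridCell]:
    """Empirical 95%-CI half-width of deviations over a depth x SNP grid.

    For every (n_reads, n_snps) combination, each sample is independently
    downsampled on both axes ``reps`` times; F_hat is recomputed from the
    downsampled X and compared against the sample's true fraction.  The
    deviations are pooled across replicates and samples before taking the
    2.5/97.5 percentiles.  Infeasible cells (target above what a sample has)
    are marked missing and the run continues.
    """
    if not read_grid or not snp_grid:
        raise ValueError("read_grid and snp_grid must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    ss = np.random.SeedSequence(seed)
    cells = []
    for n_reads in read_grid:
        for n_snps in snp_grid:
            rng = np.random.default_rng(ss.spawn(1)[0])
            devs: list[float] = []
            feasible = all(
                n_reads <= s.n_pairs * (1 + 1e-9) and n_snps <= s.n_loci
                for s in samples
            )
            if not feasible:
                logger.warning(
                    "grid cell (%g pairs, %d SNPs) infeasible; marked missing",
                    n_reads, n_snps,
                )
                cells.append(GridCell(n_reads, int(n_snps), float("nan"), 0, True))
                continue
            for _ in range(reps):
                for s in samples:
                    t = downsample_reads(s, n_reads, rng=rng)
                    t = downsample_snps(t, int(n_snps), rng=rng)
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", NegativePredictionWarning)
                        f_hat = model.predict(t.x_pct)
                    devs.append(f_hat - s.f_true_pct)
            lo, hi = np.percentile(devs, [2.5, 97.5])
            cells.append(
                GridCell(n_reads, int(n_snps), float(hi - lo) / 2.0, len(devs))
            )
    return cells


def grid_to_dataframe(cells: Iterable[GridCell]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "n_reads": c.n_reads,
                "n_snps": c.n_snps,
                "ci_half_width": c.ci_half_width,
                "n_deviations": c.n_deviations,
                "missing": c.missing,
            }
            for c in cells
        ]
    )
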