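"""Linear calibration between the non-maternal allele fraction X and the
fetal DNA fraction F.

Under the constant-error assumption — sequencing and genotyping errors
contribute a case-independent baseline of non-maternal bases — the expected
non-maternal fraction is an affine function of the true fetal fraction, so an
ordinary least-squares line

    F_hat = a * X + b        (both X and F in percent)

calibrates the estimator.  The calibration published for the Illumina
HiSeq 2000 / BeadChip platform combination is a = 18.9, b = -6.6; it ships as
:func:`published_model` but is platform-specific, so laboratories with
different chemistry should refit on their own training samples.

The API follows the statsmodels convention: :class:`FetalFractionModel` holds
the training data and ``fit()`` returns a :class:`CalibrationResults` carrying
the estimates, their standard errors and ``predict``/``summary``/JSON I/O.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainingSample:
    """One calibration point: a sample's measured X and gold-standard F."""

    sample_id: str
    x_pct: float
    f_actual_pct: float

    def __post_init__(self) -> None:
        if self.x_pct < 0 or self.f_actual_pct < 0:
            raise ValueError("X and F are percentages and must be >= 0")


class NegativePredictionWarning(UserWarning):
    """Raised when the calibration line maps an X below its root to F_hat < 0."""


class CalibrationResults:
    """Fitted (or published) calibration line with fit diagnostics.

    Parameters are on the percent scale: ``slope`` in %F per %X, ``intercept``
    in %F.  ``slope_se``/``intercept_se`` are OLS standard errors (None for a
    line not obtained by fitting, e.g. the shipped published calibration).
    """

    def __init__(
        self,
        slope: float,
        intercept: float,
        r2: Optional[float] = None,
        n_train: Optional[int] = None,
        slope_se: Optional[float] = None,
        intercept_se: Optional[float] = None,
    ) -> None:
        self.slope = float(slope)
        self.intercept = float(intercept)
        self.r2 = None if r2 is None else float(r2)
        self.n_train = n_train
        self.slope_se = None if slope_se is None else float(slope_se)
        self.intercept_se = None if intercept_se is None else float(intercept_se)
        if self.slope <= 0:
            logger.warning(
                "non-positive slope %.4g: calibration is not a sensible "
                "fetal-fraction estimator", self.slope,
            )

    # -- prediction ----------------------------------------------------
    def predict(
        self, x_pct: Union[float, Sequence[float], np.ndarray], clip_zero: bool = False
    ) -> Union[float, np.ndarray]:
        """Estimated fetal fraction F_hat = slope * X + intercept, percent.

        Negative estimates (X below the line's root) are returned as-is with a
        :class:`NegativePredictionWarning` so calibration behaviour near F ~ 0
        stays analysable; pass ``clip_zero=True`` to floor them at 0 for
        end-user reports.
        """
        x = np.asarray(x_pct, dtype=float)
        if np.any(x < 0):
            raise ValueError("X is a percentage and must be >= 0")
        f = self.slope * x + self.intercept
        if np.any(f < 0):
            if clip_zero:
                f = np.maximum(f, 0.0)
            else:
                warnings.warn(
                    "calibration produced a negative fetal-fraction estimate",
                    NegativePredictionWarning,
                    stacklevel=2,
                )
        return float(f) if np.isscalar(x_pct) else f

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "n_train": self.n_train,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationResults":
        try:
            return cls(
                slope=d["slope"],
                intercept=d["intercept"],
                r2=d.get("r2"),
                n_train=d.get("n_train"),
                slope_se=d.get("slope_se"),
                intercept_se=d.get("intercept_se"),
            )
        except (KeyError, TypeError) as exc:
            raise ValueError(f"not a calibration-model JSON object: {exc}") from exc

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResults":
        try:
            with open(path) as fh:
                d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: corrupted model JSON ({exc})") from exc
        if not isinstance(d, dict):
            raise ValueError(f"{path}: not a calibration-model JSON object")
        return cls.from_dict(d)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Fetal fraction calibration  F_hat = a*X + b  (percent scale)",
            "-" * 60,
            f"slope a      {self.slope:12.4f}"
            + (f"   (SE {self.slope_se:.4f})" if self.slope_se is not None else ""),
            f"intercept b  {self.intercept:12.4f}"
            + (f"   (SE {self.intercept_se:.4f})" if self.intercept_se is not None else ""),
        ]
        if self.r2 is not None:
            lines.append(f"R^2          {self.r2:12.4f}")
        if self.n_train is not None:
            lines.append(f"n_train      {self.n_train:12d}")
        root = -self.intercept / self.slope if self.slope else float("nan")
        lines.append(f"X at F=0     {root:12.4f} %")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"CalibrationResults(slope={self.slope:.6g}, "
            f"intercept={self.intercept:.6g}, r2={self.r2}, n_train={self.n_train})"
        )


class FetalFractionModel:
    """Calibration model: regress gold-standard F on measured X (OLS).

    Construct from arrays, :class:`TrainingSample` records
    (:meth:`from_samples`) or a DataFrame (:meth:`from_dataframe`), then call
    :meth:`fit`.
    """

    def __init__(
        self,
        x_pct: Sequence[float],
        f_actual_pct: Sequence[float],
        sample_ids: Optional[Sequence[str]] = None,
    ) -> None:
        self.x = np.asarray(x_pct, dtype=float)
        self.f = np.asarray(f_actual_pct, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.f.shape:
            raise ValueError("x_pct and f_actual_pct must be equal-length 1-D")
        if self.x.size < 2:
            raise ValueError("need at least 2 training samples")
        if np.ptp(self.x) == 0:
            raise ValueError("degenerate training set: all X values identical")
        self.sample_ids = (
            list(sample_ids)
            if sample_ids is not None
            else [f"S{i}" for i in range(self.x.size)]
        )

    @classmethod
    def from_samples(cls, samples: Iterable[TrainingSample]) -> "FetalFractionModel":
        samples = list(samples)
        return cls(
            [s.x_pct for s in samples],
            [s.f_actual_pct for s in samples],
            [s.sample_id for s in samples],
        )

    @classmethod
    def from_dataframe(
        cls, df, x_col: str = "x_pct", f_col: str = "f_actual_pct",
        id_col: Optional[str] = "sample_id",
    ) -> "FetalFractionModel":
        ids = df[id_col].astype(str).tolist() if id_col and id_col in df else None
        return cls(df[x_col].to_numpy(), df[f_col].to_numpy(), ids)

    def fit(self) -> CalibrationResults:
        """Ordinary least squares of F on X (unweighted)."""
        import statsmodels.api as sm

        res = sm.OLS(self.f, sm.add_constant(self.x)).fit()
        return CalibrationResults(
            slope=res.params[1],
            intercept=res.params[0],
            r2=res.rsquared,
            n_train=int(self.x.size),
            slope_se=res.bse[1],
            intercept_se=res.bse[0],
        )


def fit_model(samples: Iterable[TrainingSample]) -> CalibrationResults:
    """Convenience: build a :class:`FetalFractionModel` and fit it."""
    return FetalFractionModel.from_samples(samples).fit()


def published_model() -> CalibrationResults:
    """The shipped published calibration F_hat = 18.9 X - 6.6.

    Valid for the platform combination it was trained on; refit for others.
    """
    ref = resources.files("fetalfrac").joinpath("data/published_model.json")
    with resources.as_file(ref) as path:
        return CalibrationResults.load(path)
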