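"""Isoform-specific error model for replicate isoform frequencies.

Replicate scatter of an isoform frequency (a proportion) follows a bell-shaped
scaling law in the mean: the predicted replicate standard deviation is

    std(mean) = mean / (mean + (1 - mean) * alpha) - mean + b0

where ``alpha`` (> 0) sets the amplitude/shape of the curve (std collapses to
``b0`` for alpha = 1 and at mean 0 or 1) and the intercept ``b0`` (>= 0) is
the frequency-independent baseline error.  Fitted per isoform from replicate
tables, the predicted standard deviations weight the chi-square objective of
the kinetic-model fits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit
from scipy.special import gamma

from .kinetics import ISOFORMS

logger = logging.getLogger("exondef")

__all__ = [
    "ErrorModelParams",
    "predict_std",
    "fit_error_model",
    "error_symmetry_diagnostics",
    "SIGMA_FLOOR",
    "replicate_columns",
]

#: Predicted std is floored at this value when used as a chi-square weight.
SIGMA_FLOOR = 1e-4

#: Frequency column per isoform in the wide table dialect.
FREQ_COLUMNS = {"inclusion": "f_inclusion", "skipping": "f_skipping",
                "1IR": "f_1IR", "2IR": "f_2IR", "fullIR": "f_fullIR"}


def replicate_columns(isoform: str, n_replicates: int = 3) -> list[str]:
    """Column names of the replicate frequencies for one isoform."""
    return [f"{FREQ_COLUMNS[isoform]}_rep{r}" for r in range(1, n_replicates + 1)]


def predict_std(mean, alpha: float, b0: float):
    """Predicted replicate standard deviation at frequency ``mean``."""
    mean = np.asarray(mean, dtype=float)
    if np.any((mean < 0) | (mean > 1)):
        raise ValueError("mean frequency must lie in [0, 1]")
    out = mean / (mean + (1.0 - mean) * alpha) - mean + b0
    return out if out.ndim else float(out)


@dataclass
class ErrorModelParams:
    """Fitted (alpha, b0) per isoform, plus fit residual diagnostics."""

    alpha: dict[str, float]
    b0: dict[str, float]
    residual_rms: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for iso in self.alpha:
            if self.alpha[iso] <= 0:
                raise ValueError(f"alpha must be > 0 ({iso})")
            if self.b0[iso] < 0:
                raise ValueError(f"b0 must be >= 0 ({iso})")

    def std(self, isoform: str, mean) -> np.ndarray | float:
        return predict_std(mean, self.alpha[isoform], self.b0[isoform])

    def sigma(self, isoform: str, mean) -> np.ndarray | float:
        """Chi-square weight: predicted std floored at SIGMA_FLOOR."""
        return np.maximum(self.std(isoform, mean), SIGMA_FLOOR)

    def to_json(self, path=None) -> str:
        text = json.dumps({"alpha": self.alpha, "b0": self.b0}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "ErrorModelParams":
        d = json.loads(source)
        return cls(alpha=d["alpha"], b0=d["b0"])

    @classmethod
    def uniform(cls, alpha: float = 0.9, b0: float = 0.005) -> "ErrorModelParams":
        return cls(alpha={iso: alpha for iso in ISOFORMS},
                   b0={iso: b0 for iso in ISOFORMS})


def c4_factor(n) -> np.ndarray | float:
    """Finite-sample bias of the sample std: E[s] = c4(n) * sigma.

    With three replicates c4 ~ 0.886, so raw sample standard deviations
    systematically underestimate the true replicate sigma; the error-model
    fit divides by c4 to remove this bias.
    """
    n = np.asarray(n, dtype=float)
    out = np.sqrt(2.0 / (n - 1.0)) * gamma(n / 2.0) / gamma((n - 1.0) / 2.0)
    return out if out.ndim else float(out)


def _replicate_matrix(table: pd.DataFrame, isoform: str) -> np.ndarray:
    cols = [c for c in table.columns
            if c.startswith(FREQ_COLUMNS[isoform] + "_rep")]
    if not cols:
        raise ValueError(f"no replicate columns for isoform {isoform}")
    return table[sorted(cols)].to_numpy(dtype=float)


def fit_error_model(replicate_table: pd.DataFrame,
                    min_minigenes: int = 10) -> ErrorModelParams:
    """Fit (alpha, b0) per isoform from a wide replicate table.

    The table holds one row per minigene with columns
    ``f_<isoform>_rep1..repN``.  Per isoform, (mean, sample std) pairs across
    minigenes are computed and the scaling-law curve is fitted by unweighted
    nonlinear least squares.  Minigenes with fewer than two finite replicates
    are excluded with a warning.
    """
    alpha, b0, rms = {}, {}, {}
    for iso in ISOFORMS:
        reps = _replicate_matrix(replicate_table, iso)
        n_ok = np.isfinite(reps).sum(axis=1)
        if np.any(n_ok < reps.shape[1]):
            n_bad = int((n_ok < 2).sum())
            if n_bad:
                logger.warning("%s: excluding %d minigenes with <2 replicates",
                               iso, n_bad)
        keep = n_ok >= 2
        reps = reps[keep]
        if reps.shape[0] < min_minigenes:
            raise ValueError(f"need >= {min_minigenes} complete minigenes, "
                             f"got {reps.shape[0]} for {iso}")
        means = np.nanmean(reps, axis=1)
        n_rep = np.isfinite(reps).sum(axis=1)
        stds = np.nanstd(reps, axis=1, ddof=1) / c4_factor(n_rep)
        means = np.clip(means, 0.0, 1.0)
        popt, _ = curve_fit(predict_std, means, stds, p0=(0.5, 0.01),
                            bounds=([1e-6, 0.0], [np.inf, 1.0]), maxfev=20000)
        alpha[iso], b0[iso] = float(popt[0]), float(popt[1])
        rms[iso] = float(np.sqrt(np.mean((predict_std(means, *popt) - stds) ** 2)))
    return ErrorModelParams(alpha=alpha, b0=b0, residual_rms=rms)


def error_symmetry_diagnostics(replicate_table: pd.DataFrame,
                               skew_threshold: float = 0.5) -> pd.DataFrame:
    """Skewness of per-replicate deviations (replicate - minigene mean).

    Returns one row per isoform with the skewness of the pooled deviations
    and a symmetric/asymmetric verdict (|skewness| below ``skew_threshold``).
    """
    rows = []
    for iso in ISOFORMS:
        reps = _replicate_matrix(replicate_table, iso)
        means = np.nanmean(reps, axis=1, keepdims=True)
        dev = (reps - means).ravel()
        dev = dev[np.isfinite(dev)]
        skew = float(stats.skew(dev)) if dev.size > 2 else float("nan")
        rows.append({"isoform": iso, "skewness": skew,
                     "verdict": "symmetric" if abs(skew) < skew_threshold
                     else "asymmetric"})
    return pd.DataFrame(rows)
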