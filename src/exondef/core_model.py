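"""Reduced equilibrium two-step core model of the PSI-efficiency relation.

When spliceosome assembly equilibrates much faster than splicing catalysis,
the splicing outcome is set by the equilibrium occupancies of the exon
definition states.  With association constants K1, K3 for the outer exons and
K2a, K2b for the two sequential AE definition steps, the recognition
probabilities are

    alpha = K1/(1+K1),  gamma = K3/(1+K3),
    beta1 = K2a/(1+K2a+K2a*K2b),  beta2 = K2a*K2b/(1+K2a+K2a*K2b),

and, writing K2b = lambda*K2a and lumping alpha*gamma = delta**2,

    PSI        = lambda*K2a**2 / (1 + lambda*K2a**2)
    efficiency = delta**2 * (1 + lambda*K2a**2) / (1 + K2a + lambda*K2a**2)
               = delta**2 / (1 + sqrt(PSI*(1-PSI)/lambda))

The two parameters are interpretable: delta is the average recognition
probability of the constitutive exons (efficiency at extreme PSI is
delta**2) and lambda, the ratio of second- to first-step association
constants, sets the depth of the efficiency dip at PSI = 0.5.  Fitting
(lambda, delta) per condition to binned median-efficiency profiles and
comparing lambda between cancer and normal tissue quantifies how the
relative speed of the two AE definition steps shifts in cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CoreModelParams",
    "BinnedEfficiencyProfile",
    "CoreFit",
    "exon_recognition_probabilities",
    "state_frequencies",
    "core_psi_efficiency",
    "efficiency_of_psi",
    "fit_condition_pair",
]


@dataclass
class CoreModelParams:
    """(lambda, delta) of the reduced model for one condition."""

    lam: float
    delta: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (0 < self.delta <= 1):
            raise ValueError("delta must lie in (0, 1]")


def exon_recognition_probabilities(K1: float, K2a: float, K2b: float,
                                   K3: float) -> tuple[float, float, float, float]:
    """(alpha, gamma, beta1, beta2) from the four association constants."""
    if min(K1, K2a, K2b, K3) < 0:
        raise ValueError("association constants must be >= 0")
    alpha = K1 / (1.0 + K1)
    gamma = K3 / (1.0 + K3)
    denom = 1.0 + K2a + K2a * K2b
    beta1 = K2a / denom
    beta2 = K2a * K2b / denom
    return alpha, gamma, beta1, beta2


def state_frequencies(alpha: float, beta1: float, beta2: float,
                      gamma: float) -> dict[str, float]:
    """Equilibrium frequencies x_ijk of the 12 exon-definition states.

    i, k in {0, 1} mark the outer exons; j in {0, 1, 2} marks the undefined,
    partially and fully defined AE.  The splicing-active states are x_121
    (inclusion), x_101 (skipping), x_021 (first IR) and x_120 (second IR);
    all others yield fullIR.
    """
    beta0 = 1.0 - beta1 - beta2
    a = {0: 1.0 - alpha, 1: alpha}
    b = {0: beta0, 1: beta1, 2: beta2}
    g = {0: 1.0 - gamma, 1: gamma}
    return {f"x{i}{j}{k}": a[i] * b[j] * g[k]
            for i in (0, 1) for j in (0, 1, 2) for k in (0, 1)}


def core_psi_efficiency(params: CoreModelParams, K2a):
    """(PSI, efficiency) as fractions at first-step association constant K2a."""
    K2a = np.asarray(K2a, dtype=float)
    if np.any(K2a <= 0):
        raise ValueError("K2a must be positive")
    lk2 = params.lam * K2a ** 2
    psi = lk2 / (1.0 + lk2)
    eff = params.delta ** 2 * (1.0 + lk2) / (1.0 + K2a + lk2)
    if psi.ndim == 0:
        return float(psi), float(eff)
    return psi, eff


def efficiency_of_psi(params: CoreModelParams, psi):
    """Closed-form efficiency(PSI); symmetric under PSI <-> 1 - PSI."""
    psi = np.asarray(psi, dtype=float)
    if np.any((psi < 0) | (psi > 1)):
        raise ValueError("PSI must lie in [0, 1]")
    out = params.delta ** 2 / (1.0 + np.sqrt(psi * (1.0 - psi) / params.lam))
    return float(out) if out.ndim == 0 else out


@dataclass
class BinnedEfficiencyProfile:
    """Median efficiency in equal-width PSI bins (percent scale edges)."""

    bin_edges: np.ndarray            # length n_bins+1, covering [0, 100]
    median_efficiency: np.ndarray    # NaN for empty bins
    counts: np.ndarray
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "psi_bin_low": self.bin_edges[:-1],
            "psi_bin_high": self.bin_edges[1:],
            "median_efficiency": self.median_efficiency,
            "n_events": self.counts,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, condition: str = "") -> "BinnedEfficiencyProfile":
        edges = np.concatenate([frame["psi_bin_low"].to_numpy(float),
                                [float(frame["psi_bin_high"].iloc[-1])]])
        return cls(bin_edges=edges,
                   median_efficiency=frame["median_efficiency"].to_numpy(float),
                   counts=frame["n_events"].to_numpy(float),
                   condition=condition)


@dataclass
class CoreFit:
    """Joint fit of the core model to a normal/cancer profile pair."""

    normal: CoreModelParams
    cancer: CoreModelParams
    fold_change: float          # lambda_cancer / lambda_normal
    residual_rms: float
    weighted: bool = False

    def as_dict(self) -> dict:
        return {"lambda_normal": self.normal.lam, "delta_normal": self.normal.delta,
                "lambda_cancer": self.cancer.lam, "delta_cancer": self.cancer.delta,
                "fold_change": self.fold_change, "residual_rms": self.residual_rms}


_LOG10_LAM_BOUNDS = (-4.0, 4.0)
_LOG10_DELTA_BOUNDS = (-3.0, 0.0)


def _profile_data(profile: BinnedEfficiencyProfile, min_bins: int):
    ok = np.isfinite(profile.median_efficiency) & (profile.counts > 0)
    if ok.sum() < min_bins:
        raise ValueError(f"need >= {min_bins} non-empty bins, got {int(ok.sum())}")
    psi = profile.bin_centers[ok] / 100.0
    return psi, profile.median_efficiency[ok], profile.counts[ok]


def fit_condition_pair(normal: BinnedEfficiencyProfile,
                       cancer: BinnedEfficiencyProfile,
                       weighted: bool = False, min_bins: int = 4) -> CoreFit:
    """Joint least-squares fit of (lambda, delta) per condition.

    One objective with four free parameters (independent pairs per
    condition), evaluated at bin-center PSI against per-bin median
    efficiency; unweighted by default, or weighted by sqrt(bin count).
    Returns the parameters and the lambda-ratio fold change
    (lambda_cancer / lambda_normal); a fold change below 1 means an
    amplified interior efficiency drop in cancer.
    """
    psi_n, eff_n, cnt_n = _profile_data(normal, min_bins)
    psi_c, eff_c, cnt_c = _profile_data(cancer, min_bins)
    w_n = np.sqrt(cnt_n) if weighted else np.ones_like(cnt_n)
    w_c = np.sqrt(cnt_c) if weighted else np.ones_like(cnt_c)

    def residuals(theta):
        pn = CoreModelParams(10.0 ** theta[0], 10.0 ** theta[1])
        pc = CoreModelParams(10.0 ** theta[2], 10.0 ** theta[3])
        rn = (efficiency_of_psi(pn, psi_n) - eff_n) * w_n
        rc = (efficiency_of_psi(pc, psi_c) - eff_c) * w_c
        return np.concatenate([rn, rc])

    lo = [_LOG10_LAM_BOUNDS[0], _LOG10_DELTA_BOUNDS[0]] * 2
    hi = [_LOG10_LAM_BOUNDS[1], _LOG10_DELTA_BOUNDS[1]] * 2
    best = None
    for lam0 in (-2.0, -1.0, 0.0):
        theta0 = [lam0, -0.02, lam0, -0.02]
        sol = least_squares(residuals, theta0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    theta = best.x
    pn = CoreModelParams(10.0 ** theta[0], 10.0 ** theta[1])
    pc = CoreModelParams(10.0 ** theta[2], 10.0 ** theta[3])
    n_pts = len(psi_n) + len(psi_c)
    return CoreFit(normal=pn, cancer=pc, fold_change=pc.lam / pn.lam,
                   residual_rms=float(np.sqrt(2 * best.cost / n_pts)),
                   weighted=weighted)
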