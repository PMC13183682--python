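"""Closed-form n-step toy models of alternative-exon recognition.

The toy models isolate the AE recognition chain: the outer exons are taken as
constitutively defined, and a single initial species (AE undefined) progresses
through ``n`` irreversible recognition steps to the fully defined AE.  The
rate of the i-th step is ``alpha**(i-1) * k2``, so ``alpha < 1`` means late
spliceosome assembly steps are slower than early ones (efficient
proofreading).  Skipping arises from the undefined species and inclusion from
the fully defined species (both at rate ``kspl``); every chain species can
exit as intron retention (rate ``kret``).

At steady state PSI is a Hill-like function of ``k2``:

    PSI(k2) = a k2^n / (a k2^n + (kspl+kret) * prod_{i=1..n-1}(alpha^i k2 + kret))

with ``a = alpha**(n(n-1)/2)``, and the effective Hill coefficient is
estimated from the 10%/90% switching points as h = log(81)/log(k2_90/k2_10).
For n = 1 the efficiency kspl/(kspl+kret) is independent of k2; for n >= 2
the retention-prone intermediates open an efficiency dip at intermediate PSI
-- the switching/efficiency trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "ToyParameters",
    "ToyDoseResponse",
    "toy_psi_efficiency",
    "hill_coefficient",
    "dose_response",
    "sampling_study",
]


@dataclass
class ToyParameters:
    """Rates of the n-step AE recognition toy model (time unit arbitrary)."""

    kspl: float = 1.0
    kret: float = 0.2
    alpha: float = 1.0 / 30.0
    n_steps: int = 1

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if min(self.kspl, self.kret, self.alpha) <= 0:
            raise ValueError("all toy rates must be positive")


@dataclass
class ToyDoseResponse:
    """k2 sweep summary of one toy model."""

    params: ToyParameters
    k2_grid: np.ndarray
    psi: np.ndarray
    efficiency: np.ndarray
    k2_10: float
    k2_90: float
    hill: float
    switching_fold: float
    min_efficiency: float
    limit_efficiency: float = field(default=math.nan)


def _chain_steady_state(params: ToyParameters, k2: float) -> np.ndarray:
    """Steady-state abundances of the n+1 chain species (undefined .. defined)."""
    n = params.n_steps
    kspl, kret, alpha = params.kspl, params.kret, params.alpha
    x = np.empty(n + 1)
    x[0] = 1.0 / (kspl + kret + k2)
    for i in range(1, n):
        x[i] = (alpha ** (i - 1)) * k2 * x[i - 1] / ((alpha ** i) * k2 + kret)
    x[n] = (alpha ** (n - 1)) * k2 * x[n - 1] / (kspl + kret)
    return x


def toy_psi_efficiency(params: ToyParameters, k2: float) -> tuple[float, float]:
    """Closed-form steady-state (PSI, efficiency) at recognition rate ``k2``.

    PSI = inclusion/(inclusion+skipping) as a fraction; efficiency =
    productive/(productive+retention).
    """
    if k2 <= 0:
        raise ValueError("k2 must be positive")
    x = _chain_steady_state(params, k2)
    kspl, kret = params.kspl, params.kret
    productive = kspl * (x[0] + x[-1])
    retention = kret * x.sum()
    psi = x[-1] / (x[0] + x[-1])
    efficiency = productive / (productive + retention)
    return psi, efficiency


def hill_coefficient(k2_10: float, k2_90: float) -> float:
    """Effective Hill coefficient h = log(81) / log(k2_90 / k2_10)."""
    if not (k2_90 > k2_10 > 0):
        raise ValueError("requires k2_90 > k2_10 > 0")
    return math.log(81.0) / math.log(k2_90 / k2_10)


def _find_k2_at_psi(params: ToyParameters, target: float,
                    lo: float, hi: float, tol: float) -> float:
    """Bisection on the monotone PSI(k2), auto-expanding the bracket."""
    f = lambda logk: toy_psi_efficiency(params, 10.0 ** logk)[0] - target
    llo, lhi = math.log10(lo), math.log10(hi)
    for _ in range(200):
        if f(llo) < 0:
            break
        llo -= 1.0
    for _ in range(200):
        if f(lhi) > 0:
            break
        lhi += 1.0
    if not (f(llo) < 0 < f(lhi)):
        raise ValueError(f"could not bracket PSI={target}")
    root = brentq(f, llo, lhi, xtol=tol, rtol=tol)
    return 10.0 ** root


def dose_response(params: ToyParameters, k2_range: tuple[float, float] = (1e-4, 1e4),
                  tol: float = 1e-8, n_grid: int = 200) -> ToyDoseResponse:
    """Sweep k2, locate the 10%/90% switching points and summarize.

    Returns the Hill coefficient, the switching fold k2_90/k2_10 and the
    minimal efficiency over the whole k2 range (the k2->0 / k2->inf limits
    both equal kspl/(kspl+kret); any interior minimum is found numerically).
    """
    lo, hi = k2_range
    k2_10 = _find_k2_at_psi(params, 0.10, lo, hi, tol)
    k2_90 = _find_k2_at_psi(params, 0.90, lo, hi, tol)
    h = hill_coefficient(k2_10, k2_90)

    grid = np.geomspace(min(lo, k2_10 / 100), max(hi, k2_90 * 100), n_grid)
    pe = np.array([toy_psi_efficiency(params, k2) for k2 in grid])
    psi, eff = pe[:, 0], pe[:, 1]
    if np.any(np.diff(psi) <= 0):
        raise AssertionError("PSI(k2) must be strictly increasing")

    limit_eff = params.kspl / (params.kspl + params.kret)
    i_min = int(np.argmin(eff))
    min_eff = float(eff[i_min])
    if 0 < i_min < len(grid) - 1:
        res = minimize_scalar(
            lambda logk: toy_psi_efficiency(params, 10.0 ** logk)[1],
            bracket=(math.log10(grid[i_min - 1]), math.log10(grid[i_min]),
                     math.log10(grid[i_min + 1])))
        min_eff = min(min_eff, float(res.fun))
    min_eff = min(min_eff, limit_eff)

    return ToyDoseResponse(params=params, k2_grid=grid, psi=psi, efficiency=eff,
                           k2_10=k2_10, k2_90=k2_90, hill=h,
                           switching_fold=k2_90 / k2_10, min_efficiency=min_eff,
                           limit_efficiency=limit_eff)


def sampling_study(base: ToyParameters | None = None, n_samples: int = 2000,
                   sd_log: float = 0.5, seed: int = 0,
                   n_steps_range: tuple[int, ...] = tuple(range(1, 8))):
    """Random-sampling study of the switching/efficiency trade-off.

    ``kspl``, ``kret`` and ``alpha`` are drawn log-normally around the base
    values (standard deviation ``sd_log`` of the natural log); for each sample
    and each step count the dose response is computed.  Returns a pandas
    DataFrame with columns (sample, n_steps, kspl, kret, alpha, hill,
    switching_fold, min_efficiency); failed samples are recorded with NaNs.
    """
    import pandas as pd

    if base is None:
        base = ToyParameters()
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.normal(0.0, sd_log, size=(n_samples, 3))) if sd_log > 0 \
        else np.ones((n_samples, 3))
    rows = []
    for s in range(n_samples):
        kspl = base.kspl * draws[s, 0]
        kret = base.kret * draws[s, 1]
        alpha = base.alpha * draws[s, 2]
        for n in n_steps_range:
            p = ToyParameters(kspl=kspl, kret=kret, alpha=alpha, n_steps=n)
            try:
                dr = dose_response(p)
                rows.append((s, n, kspl, kret, alpha, dr.hill,
                             dr.switching_fold, dr.min_efficiency))
            except (ValueError, AssertionError):
                rows.append((s, n, kspl, kret, alpha,
                             math.nan, math.nan, math.nan))
    return pd.DataFrame(rows, columns=["sample", "n_steps", "kspl", "kret",
                                       "alpha", "hill", "switching_fold",
                                       "min_efficiency"])
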