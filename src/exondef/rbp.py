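"""RBP regulatory-mode selection by model discrimination.

An RNA-binding protein (RBP) may modulate any non-empty subset of the four
exon-definition steps of the two-step model (k1, k2a, k2b, k3), giving
2^4 - 1 = 15 model variants.  A knockdown (KD) multiplies every flagged rate
by a common fold-change epsilon:

    k_x,KD = epsilon**flag_x * k_x

Each variant is fitted to the five isoform frequencies of the unmutated
minigene under KD (one-dimensional fit of epsilon; all other parameters
frozen at the control fit), then cross-validated by predicting the mutant
panel under KD with no refitting, reusing the control-fit mutation
fold-changes.  Variants are ranked by prediction RMSE (primary) and fit RMSE
(secondary); chi-square scores relative to the 95% critical value are
reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist

from .fitting import FitResult, MutagenesisDataset, predict_frequencies
from .kinetics import KineticParameters

logger = logging.getLogger("exondef")

__all__ = [
    "RegulatoryMode",
    "enumerate_variants",
    "fit_variant",
    "cross_validate",
    "rank_variants",
    "select_mode",
    "VariantFit",
]

_STEP_NAMES = ("k1", "k2a", "k2b", "k3")

_LOG10_EPS_BOUNDS = (-3.0, 3.0)


@dataclass(frozen=True)
class RegulatoryMode:
    """Binary flags marking which definition steps an RBP modulates."""

    k1: int = 0
    k2a: int = 0
    k2b: int = 0
    k3: int = 0

    def __post_init__(self) -> None:
        if not any(self.flags):
            raise ValueError("null variant excluded: at least one flag must be set")

    @property
    def flags(self) -> tuple[int, int, int, int]:
        return (self.k1, self.k2a, self.k2b, self.k3)

    @property
    def bitstring(self) -> str:
        """4-character bitstring over (k1, k2a, k2b, k3)."""
        return "".join(str(f) for f in self.flags)

    def apply(self, params: KineticParameters, epsilon: float) -> KineticParameters:
        """Scale every flagged rate by epsilon."""
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        factors = {name: epsilon for name, flag in zip(_STEP_NAMES, self.flags) if flag}
        return params.scaled(**factors)


def enumerate_variants(n_modulatable_steps: int = 4) -> list[RegulatoryMode]:
    """All 2^n - 1 non-empty flag subsets in ascending binary order."""
    n = n_modulatable_steps
    if n < 1 or n > 4:
        raise ValueError("n_modulatable_steps must be in 1..4")
    variants = []
    for v in range(1, 2 ** n):
        bits = [(v >> (n - 1 - i)) & 1 for i in range(n)]
        bits = bits + [0] * (4 - n)
        variants.append(RegulatoryMode(*bits))
    return variants


@dataclass
class VariantFit:
    """Fitted epsilon and scores of one regulatory-mode variant."""

    mode: RegulatoryMode
    epsilon: float
    fit_chi2: float
    fit_rmse: float
    identifiable: bool = True


def _freq_and_scores(variant, params, exons, folds, X, sigma):
    Y = predict_frequencies(variant, params, exons, folds)
    resid = (X - Y) / sigma
    return Y, float(np.sum(resid ** 2)), float(np.sqrt(np.mean((X - Y) ** 2)))


def fit_variant(mode: RegulatoryMode, control_fit: FitResult | KineticParameters,
                kd_wt_frequencies: np.ndarray, sigma: np.ndarray) -> VariantFit:
    """One-dimensional fit of epsilon to the 5 KD WT isoform frequencies.

    All kinetic parameters stay frozen at the control fit; epsilon is
    optimized on a log scale with chi-square weighting.  A variant whose
    epsilon has no effect on the outputs is flagged non-identifiable.
    """
    params = control_fit.params if isinstance(control_fit, FitResult) else control_fit
    variant = params.variant
    X = np.asarray(kd_wt_frequencies, float).reshape(1, 5)
    S = np.asarray(sigma, float).reshape(1, 5)

    def objective(log_eps: float) -> float:
        kd = mode.apply(params, 10.0 ** log_eps)
        _, chi2, _ = _freq_and_scores(variant, kd, [""], np.ones(1), X, S)
        return chi2

    res = minimize_scalar(objective, bounds=_LOG10_EPS_BOUNDS, method="bounded",
                          options={"xatol": 1e-10})
    eps = float(10.0 ** res.x)
    # identifiability probe: does epsilon move the outputs at all?
    probe = abs(objective(res.x + 0.5) - res.fun) + abs(objective(res.x - 0.5) - res.fun)
    identifiable = probe > 1e-12
    if not identifiable:
        logger.warning("variant %s: epsilon has no effect (non-identifiable)",
                       mode.bitstring)
    kd = mode.apply(params, eps)
    _, chi2, rmse = _freq_and_scores(variant, kd, [""], np.ones(1), X, S)
    return VariantFit(mode=mode, epsilon=eps, fit_chi2=chi2, fit_rmse=rmse,
                      identifiable=identifiable)


def cross_validate(variant_fit: VariantFit, control_fit: FitResult,
                   kd_mutant_data: MutagenesisDataset) -> dict:
    """Predict all mutant isoform frequencies under KD, with no refitting.

    Mutation fold-changes from the control fit are assumed unchanged by the
    KD; mutants absent from the control fit are skipped with a warning.
    The critical chi-square uses df = number of predicted points (no
    parameters are fitted at this stage) at 95% confidence.
    """
    params = control_fit.params
    kd = variant_fit.mode.apply(params, variant_fit.epsilon)
    ids = [m for m in kd_mutant_data.mutant_ids
           if m in control_fit.fold_changes.index]
    missing = set(kd_mutant_data.mutant_ids) - set(ids)
    if missing:
        logger.warning("skipping %d KD mutants absent from control fit",
                       len(missing))
    rows = [kd_mutant_data.table.index.get_loc(m) for m in ids]
    exons = [kd_mutant_data.exons[r] for r in rows]
    folds = control_fit.fold_changes.loc[ids].to_numpy()
    X = kd_mutant_data.frequencies[rows]
    S = kd_mutant_data.sigmas[rows]
    _, chi2, rmse = _freq_and_scores(params.variant, kd, exons, folds, X, S)
    n_points = X.size
    crit = float(chi2_dist.ppf(0.95, df=n_points))
    return {"prediction_chi2": chi2, "prediction_rmse": rmse,
            "chi2_over_critical": chi2 / crit, "n_predicted_points": n_points,
            "n_skipped": len(missing)}


def rank_variants(table: pd.DataFrame) -> pd.DataFrame:
    """Rank a selection table: prediction RMSE primary, fit RMSE secondary.

    Adds ``rank`` (competition ranking; ties share a rank) and
    ``rank_chi2`` (the chi-square-based ranking) columns.
    """
    t = table.copy()
    key = list(zip(t["prediction_rmse"].round(12), t["fit_rmse"].round(12)))
    order = sorted(set(key))
    rank_of = {}
    r = 1
    for k in order:
        rank_of[k] = r
        r += key.count(k)
    t["rank"] = [rank_of[k] for k in key]
    chi_key = list(zip(t["prediction_chi2"].round(12), t["fit_chi2"].round(12)))
    chi_order = sorted(set(chi_key))
    chi_rank_of = {}
    r = 1
    for k in chi_order:
        chi_rank_of[k] = r
        r += chi_key.count(k)
    t["rank_chi2"] = [chi_rank_of[k] for k in chi_key]
    return t.sort_values("rank", kind="stable")


def select_mode(control_fit: FitResult, kd_data: MutagenesisDataset,
                n_steps: int = 4) -> pd.DataFrame:
    """Fit all 15 variants to the KD WT record, cross-validate and rank.

    Returns the ranked selection table (one row per variant) with fitted
    epsilon, fit/prediction RMSE and chi-square scores, and both rankings.
    """
    wt_row = kd_data.table.index.get_loc(kd_data.wt_id)
    kd_wt = kd_data.frequencies[wt_row]
    sigma = kd_data.sigmas[wt_row]
    fit_crit = float(chi2_dist.ppf(0.95, df=4))  # 5 frequencies - 1 parameter
    rows = []
    for mode in enumerate_variants(n_steps):
        vfit = fit_variant(mode, control_fit, kd_wt, sigma)
        cv = cross_validate(vfit, control_fit, kd_data)
        rows.append({"mode": mode.bitstring, "epsilon": vfit.epsilon,
                     "fit_chi2": vfit.fit_chi2, "fit_rmse": vfit.fit_rmse,
                     "fit_chi2_over_critical": vfit.fit_chi2 / fit_crit,
                     "identifiable": vfit.identifiable, **cv})
    return rank_variants(pd.DataFrame(rows))
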