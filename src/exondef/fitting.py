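"""Joint chi-square fitting of the exon-definition models to mutagenesis data.

A mutagenesis dataset holds the wild-type (WT) minigene plus M single-mutant
records, each with mean frequencies of the five isoforms.  Every mutation is
assigned to the definition rate of its residing (exonic) or nearest
(intronic) exon and acts as one multiplicative fold-change on that rate; in
the two-step model an AE mutation scales ``k2a`` and ``k2b`` by the same
factor, leaving their ratio unchanged.  The shared kinetic parameters (9 for
the one-step, 10 for the two-step model; dissociation rates and synthesis
fixed) and the M fold-changes are optimized jointly in log10 space by
minimizing

    chi^2 = sum over records and isoforms of ((X - Y) / sigma)^2

with sigma supplied by the isoform-specific error model evaluated at the data
means.  A Latin-hypercube multistart explores the shared-parameter space; the
Jacobian is sparse (each mutant's residual block depends only on the shared
parameters and its own fold-change), which keeps the joint fit fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize_scalar
from scipy.sparse import lil_matrix
from scipy.stats import qmc

from .error_model import FREQ_COLUMNS, ErrorModelParams
from .kinetics import (ISOFORMS, KineticParameters, build_model,
                       isoform_frequencies, steady_state)

logger = logging.getLogger("exondef")

__all__ = [
    "MinigeneAnnotation",
    "MutagenesisDataset",
    "FitResult",
    "assign_mutation_to_exon",
    "chi_square",
    "fit_model",
    "psi_efficiency_curve",
    "count_fit_dimensions",
    "SHARED_FREE_PARAMS",
    "predict_frequencies",
]

#: Shared free parameters per variant; k4, k5(a,b), k6 and s stay fixed.
SHARED_FREE_PARAMS = {
    "one_step": ("k1", "k2", "k3", "kspli", "kret",
                 "kincl", "kskip", "kdr1", "kdr2"),
    "two_step": ("k1", "k2a", "k2b", "k3", "kspli", "kret",
                 "kincl", "kskip", "kdr1", "kdr2"),
}

#: Exon assignment -> affected definition rates.
EXON_RATES = {
    "one_step": {"exon1": ("k1",), "AE": ("k2",), "exon3": ("k3",)},
    "two_step": {"exon1": ("k1",), "AE": ("k2a", "k2b"), "exon3": ("k3",)},
}

_LOG10_BOUNDS = (-5.0, 2.0)       # Latin-hypercube box for shared rates
_LOG10_FOLD_BOUNDS = (-4.0, 4.0)  # per-mutation fold-change box


@dataclass
class MinigeneAnnotation:
    """Exon boundaries of the three-exon minigene (1-based, inclusive).

    The default layout mirrors a short-intron minigene: a 147-nt AE flanked
    by 87-nt and 80-nt introns.  ``ae_window`` widens the AE assignment into
    the introns (-40 nt upstream of the AE 3'SS, +40 nt downstream of the AE
    5'SS).
    """

    exon1: tuple[int, int] = (1, 180)
    exon2: tuple[int, int] = (268, 414)
    exon3: tuple[int, int] = (495, 700)
    ae_window: int = 40

    @property
    def length(self) -> int:
        return self.exon3[1]


def assign_mutation_to_exon(position: int, annotation: MinigeneAnnotation) -> str:
    """Map a mutation position to 'exon1', 'AE' or 'exon3'.

    Exonic positions map to their exon; intronic positions within the AE
    window map to the AE; remaining intron interiors go to the nearest
    flanking exon, with midpoint ties broken toward the AE (logged).
    """
    a = annotation
    if not (a.exon1[0] <= position <= a.exon3[1]):
        raise ValueError(f"position {position} outside minigene [{a.exon1[0]}, {a.exon3[1]}]")
    if a.exon1[0] <= position <= a.exon1[1]:
        return "exon1"
    if a.exon2[0] <= position <= a.exon2[1]:
        return "AE"
    if a.exon3[0] <= position <= a.exon3[1]:
        return "exon3"
    if position < a.exon2[0]:  # intron 1
        if a.exon2[0] - position <= a.ae_window:
            return "AE"
        d_outer, d_ae = position - a.exon1[1], a.exon2[0] - position
        other = "exon1"
    else:  # intron 2
        if position - a.exon2[1] <= a.ae_window:
            return "AE"
        d_outer, d_ae = a.exon3[0] - position, position - a.exon2[1]
        other = "exon3"
    if d_ae == d_outer:
        logger.info("position %d at intron midpoint; tie broken toward AE", position)
        return "AE"
    return "AE" if d_ae < d_outer else other


def chi_square(model_outputs: np.ndarray, data: np.ndarray,
               stds: np.ndarray) -> float:
    """chi^2 = sum ((X - Y) / sigma)^2 over all records and isoforms."""
    Y = np.asarray(model_outputs, float)
    X = np.asarray(data, float)
    s = np.asarray(stds, float)
    if Y.shape != X.shape or X.shape != s.shape:
        raise ValueError("mismatched shapes")
    if np.any(s <= 0):
        raise ValueError("all sigma must be positive")
    return float(np.sum(((X - Y) / s) ** 2))


_F_COLS = [FREQ_COLUMNS[iso] for iso in ISOFORMS]
_S_COLS = ["sigma_" + iso for iso in ISOFORMS]


@dataclass
class MutagenesisDataset:
    """WT + M mutant records with frequencies, sigmas and exon assignments.

    ``table`` is indexed by minigene id (the WT row first) with columns
    ``mutation_position`` (NaN for WT), ``exon`` ('' for WT), the five
    frequency columns and the five sigma columns.
    """

    table: pd.DataFrame
    annotation: MinigeneAnnotation = field(default_factory=MinigeneAnnotation)
    wt_id: str = "WT"

    @property
    def mutant_ids(self) -> list[str]:
        return [i for i in self.table.index if i != self.wt_id]

    @property
    def n_mutants(self) -> int:
        return len(self.mutant_ids)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table[_F_COLS].to_numpy(float)

    @property
    def sigmas(self) -> np.ndarray:
        return self.table[_S_COLS].to_numpy(float)

    @property
    def exons(self) -> list[str]:
        return self.table["exon"].tolist()

    @classmethod
    def from_frequencies(cls, freq_table: pd.DataFrame,
                         error_model: ErrorModelParams,
                         annotation: MinigeneAnnotation | None = None,
                         wt_id: str = "WT",
                         sum_tolerance: float = 0.02) -> "MutagenesisDataset":
        """Build a dataset from a raw frequency table.

        ``freq_table`` is indexed by minigene id with ``mutation_position``
        (NaN for WT) and the five ``f_*`` frequency columns.  Rows whose
        frequencies deviate from 1 by more than ``sum_tolerance`` are
        rejected; the rest are renormalized to sum exactly to 1.  Sigmas come
        from the error model evaluated at the (renormalized) means.
        """
        annotation = annotation or MinigeneAnnotation()
        tab = freq_table.copy()
        if wt_id not in tab.index:
            raise ValueError(f"WT record {wt_id!r} missing")
        sums = tab[_F_COLS].sum(axis=1)
        bad = (sums - 1.0).abs() > sum_tolerance
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records with frequency sum "
                             f"off by > {sum_tolerance}")
        tab[_F_COLS] = tab[_F_COLS].div(sums, axis=0)
        exons = []
        for mid, row in tab.iterrows():
            pos = row.get("mutation_position", np.nan)
            if mid == wt_id or pd.isna(pos):
                exons.append("")
            else:
                exons.append(assign_mutation_to_exon(int(pos), annotation))
        tab["exon"] = exons
        for iso, fcol, scol in zip(ISOFORMS, _F_COLS, _S_COLS):
            tab[scol] = error_model.sigma(iso, tab[fcol].to_numpy(float))
        order = [wt_id] + [i for i in tab.index if i != wt_id]
        return cls(table=tab.loc[order], annotation=annotation, wt_id=wt_id)

    @classmethod
    def read_tsv(cls, path, error_model: ErrorModelParams,
                 annotation: MinigeneAnnotation | None = None,
                 wt_id: str = "WT") -> "MutagenesisDataset":
        tab = pd.read_csv(path, sep="\t", index_col="minigene_id")
        return cls.from_frequencies(tab, error_model, annotation, wt_id)


@dataclass
class FitResult:
    """Best fit of one model variant to a mutagenesis dataset."""

    variant: str
    params: KineticParameters
    fold_changes: pd.Series
    chi2: float
    rmse: float
    residuals: pd.DataFrame
    start_chi2: list[float]
    success: bool
    n_data_points: int
    n_free_parameters: int
    start_index: int = 0

    def to_json(self, path=None) -> str:
        import json
        payload = {
            "variant": self.variant,
            "params": {k: v for k, v in self.params.as_dict().items()
                       if v is not None},
            "fold_changes": self.fold_changes.to_dict(),
            "chi2": self.chi2, "rmse": self.rmse, "success": self.success,
            "n_data_points": self.n_data_points,
            "n_free_parameters": self.n_free_parameters,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class _BatchedSteadyState:
    """Batched steady-state frequencies for records differing in a few rates.

    Precomputes per-rate structure matrices S_r with A = sum_r value_r * S_r,
    so that a whole dataset's steady states reduce to one stacked
    ``np.linalg.solve``.
    """

    def __init__(self, variant: str):
        dummy = dict.fromkeys(SHARED_FREE_PARAMS[variant], 1.0)
        params = KineticParameters(**dummy)
        self.variant = variant
        self.model = build_model(variant, params)
        n = len(self.model.species)
        self.n_species = n
        self.iso_idx = self.model.isoform_indices
        mats: dict[str, np.ndarray] = {}
        self.b_unit = np.zeros(n)
        for name, _rate, src, dst in self.model.reactions:
            if src is None:
                self.b_unit[dst] += 1.0  # synthesis, scaled by s
                continue
            S = mats.setdefault(name, np.zeros((n, n)))
            S[src, src] -= 1.0
            if dst is not None:
                S[dst, src] += 1.0
        self.rate_names = sorted(mats)
        self.S = np.stack([mats[r] for r in self.rate_names])

    def frequencies(self, rate_values: dict[str, np.ndarray], s: float) -> np.ndarray:
        """(R, 5) isoform frequencies for R records of per-rate values."""
        R = len(next(iter(rate_values.values())))
        vals = np.empty((R, len(self.rate_names)))
        for j, name in enumerate(self.rate_names):
            v = rate_values[name]
            vals[:, j] = v
        A = np.tensordot(vals, self.S, axes=(1, 0))
        b = np.broadcast_to(self.b_unit * s, (R, self.n_species))
        x = np.linalg.solve(-A, b[..., None])[..., 0]
        iso = x[:, self.iso_idx]
        totals = iso.sum(axis=1, keepdims=True)
        return iso / totals


def _rate_values_for_records(variant: str, shared: dict[str, float],
                             exons: list[str], folds: np.ndarray,
                             fixed: dict[str, float]) -> dict[str, np.ndarray]:
    R = len(exons)
    values = {}
    for name in SHARED_FREE_PARAMS[variant]:
        values[name] = np.full(R, shared[name])
    for name, v in fixed.items():
        values[name] = np.full(R, v)
    for r, exon in enumerate(exons):
        if exon:
            for rate in EXON_RATES[variant][exon]:
                values[rate][r] *= folds[r]
    return values


def _fixed_rates(variant: str) -> dict[str, float]:
    if variant == "one_step":
        return {"k4": 0.01, "k5": 0.01, "k6": 0.01}
    return {"k4": 0.01, "k5a": 0.01, "k5b": 0.01, "k6": 0.01}


def predict_frequencies(variant: str, params: KineticParameters,
                        exons: list[str], folds: np.ndarray,
                        batch: _BatchedSteadyState | None = None) -> np.ndarray:
    """(R, 5) model isoform frequencies for records with given fold-changes."""
    batch = batch or _BatchedSteadyState(variant)
    shared = {n: getattr(params, n) for n in SHARED_FREE_PARAMS[variant]}
    fixed = {n: getattr(params, n) for n in _fixed_rates(variant)}
    vals = _rate_values_for_records(variant, shared, exons, np.asarray(folds, float), fixed)
    return batch.frequencies(vals, params.s)


def count_fit_dimensions(dataset: MutagenesisDataset, variant: str) -> tuple[int, int]:
    """(number of fitted data points, number of free parameters)."""
    M = dataset.n_mutants
    return (M + 1) * 5, len(SHARED_FREE_PARAMS[variant]) + M


def _make_result(variant, dataset, shared_log10, folds_log10, start_chi2,
                 success, start_index, batch) -> FitResult:
    names = SHARED_FREE_PARAMS[variant]
    shared = {n: 10.0 ** v for n, v in zip(names, shared_log10)}
    params = KineticParameters(**shared, **_fixed_rates(variant))
    folds = np.concatenate([[1.0], 10.0 ** folds_log10])
    Y = predict_frequencies(variant, params, dataset.exons, folds, batch)
    X, S = dataset.frequencies, dataset.sigmas
    resid = (X - Y) / S
    chi2 = float(np.sum(resid ** 2))
    rmse = float(np.sqrt(np.mean((X - Y) ** 2)))
    res_df = pd.DataFrame(X - Y, index=dataset.table.index, columns=list(ISOFORMS))
    n_pts, n_free = count_fit_dimensions(dataset, variant)
    return FitResult(variant=variant, params=params,
                     fold_changes=pd.Series(folds[1:], index=dataset.mutant_ids),
                     chi2=chi2, rmse=rmse, residuals=res_df,
                     start_chi2=start_chi2, success=success,
                     n_data_points=n_pts, n_free_parameters=n_free,
                     start_index=start_index)


def fit_model(variant: str, dataset: MutagenesisDataset, n_starts: int = 20,
              seed: int = 0, mode: str = "joint",
              max_nfev: int = 400) -> FitResult:
    """Fit a model variant to a mutagenesis dataset.

    ``mode='joint'`` optimizes all shared parameters and fold-changes
    together (Latin-hypercube multistart over the shared log10 rates, fold
    starts at 1).  ``mode='profile'`` is a fast approximation for tests: the
    shared parameters are fitted to the WT record only, then each mutation's
    fold-change is fitted one-dimensionally.  The WT fold-change is pinned to
    1, which resolves the fold/rate scaling degeneracy.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    names = SHARED_FREE_PARAMS[variant]
    p = len(names)
    M = dataset.n_mutants
    exons = dataset.exons
    X, S = dataset.frequencies, dataset.sigmas
    batch = _BatchedSteadyState(variant)
    fixed = _fixed_rates(variant)
    s_rate = 0.001

    def residuals(theta):
        shared = {n: 10.0 ** v for n, v in zip(names, theta[:p])}
        folds = np.concatenate([[1.0], 10.0 ** theta[p:]])
        vals = _rate_values_for_records(variant, shared, exons, folds, fixed)
        Y = batch.frequencies(vals, s_rate)
        return ((X - Y) / S).ravel()

    rng = np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=p, seed=rng)
    lo, hi = _LOG10_BOUNDS
    starts = qmc.scale(sampler.random(n_starts), lo, hi)
    # a physiologically plausible centre start replaces the first sample
    starts[0] = np.log10([0.02 if n.startswith("k2") else
                          0.05 if n in ("k1", "k3") else
                          0.1 if n == "kspli" else 0.003
                          for n in names])

    if mode == "profile":
        return _fit_profile(variant, dataset, starts, batch)
    if mode != "joint":
        raise ValueError(f"unknown mode {mode!r}")

    sparsity = lil_matrix(((M + 1) * 5, p + M), dtype=int)
    sparsity[:, :p] = 1
    for j in range(M):
        sparsity[(j + 1) * 5:(j + 2) * 5, p + j] = 1

    lb = np.concatenate([np.full(p, lo), np.full(M, _LOG10_FOLD_BOUNDS[0])])
    ub = np.concatenate([np.full(p, hi), np.full(M, _LOG10_FOLD_BOUNDS[1])])
    best = None
    start_chi2: list[float] = []
    any_success = False
    for i, st in enumerate(starts):
        theta0 = np.concatenate([st, np.zeros(M)])
        try:
            sol = least_squares(residuals, theta0, bounds=(lb, ub),
                                jac_sparsity=sparsity, method="trf",
                                max_nfev=max_nfev, x_scale="jac")
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("start %d failed: %s", i, exc)
            start_chi2.append(np.inf)
            continue
        chi2 = float(2 * sol.cost)
        start_chi2.append(chi2)
        any_success = any_success or sol.success
        if best is None or chi2 < best[0]:
            best = (chi2, sol.x, i)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    if not any_success:
        logger.warning("optimizer did not formally converge on any start; "
                       "returning best-effort result")
    _chi2, theta, start_index = best
    return _make_result(variant, dataset, theta[:p], theta[p:], start_chi2,
                        any_success, start_index, batch)


def _fit_profile(variant, dataset, starts, batch) -> FitResult:
    """Fast two-stage fit: shared params on WT, then 1-D fold fits."""
    names = SHARED_FREE_PARAMS[variant]
    p = len(names)
    X, S = dataset.frequencies, dataset.sigmas
    fixed = _fixed_rates(variant)
    lo, hi = _LOG10_BOUNDS

    def wt_residuals(theta):
        shared = {n: 10.0 ** v for n, v in zip(names, theta)}
        vals = _rate_values_for_records(variant, shared, [""], np.ones(1), fixed)
        Y = batch.frequencies(vals, 0.001)
        return ((X[:1] - Y) / S[:1]).ravel()

    best = None
    start_chi2 = []
    for i, st in enumerate(starts):
        sol = least_squares(wt_residuals, st, bounds=(lo, hi), method="trf")
        chi2 = float(2 * sol.cost)
        start_chi2.append(chi2)
        if best is None or chi2 < best[0]:
            best = (chi2, sol.x, i)
    _chi2, theta, start_index = best
    shared = {n: 10.0 ** v for n, v in zip(names, theta)}
    params = KineticParameters(**shared, **fixed)

    folds_log10 = np.zeros(dataset.n_mutants)
    for j, mid in enumerate(dataset.mutant_ids):
        row = j + 1
        exon = dataset.exons[row]

        def one_mut(logf):
            vals = _rate_values_for_records(variant, shared, [exon],
                                            np.array([10.0 ** logf]), fixed)
            Y = batch.frequencies(vals, 0.001)
            return float(np.sum(((X[row] - Y[0]) / S[row]) ** 2))

        res = minimize_scalar(one_mut, bounds=_LOG10_FOLD_BOUNDS,
                              method="bounded",
                              options={"xatol": 1e-10})
        folds_log10[j] = res.x
    return _make_result(variant, dataset, theta, folds_log10, start_chi2,
                        True, start_index, batch)


def psi_efficiency_curve(params: KineticParameters | FitResult,
                         variant: str | None = None,
                         fold_range: tuple[float, float] = (1e-3, 1e3),
                         n_points: int = 121) -> pd.DataFrame:
    """Efficiency-vs-PSI locus swept over the AE recognition fold-change.

    The AE rate (``k2``, or proportionally ``k2a`` and ``k2b``) is scaled
    over ``fold_range``; fold-change 1 reproduces the fitted WT point.
    Returns a DataFrame with columns fold, psi (percent), efficiency.
    """
    if isinstance(params, FitResult):
        variant = params.variant
        params = params.params
    if variant is None:
        variant = params.variant
    rates = EXON_RATES[variant]["AE"]
    folds = np.geomspace(fold_range[0], fold_range[1], n_points)
    rows = []
    for f in folds:
        scaled = params.scaled(**{r: f for r in rates})
        model = build_model(variant, scaled)
        dist = isoform_frequencies(model, steady_state(model))
        rows.append((f, dist.psi, dist.efficiency))
    return pd.DataFrame(rows, columns=["fold", "psi", "efficiency"])
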