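"""Filtering, quantification and coordination statistics for LSV tables.

A local splice variation (LSV) is a set of splice junctions sharing a common
exon boundary, quantified as event frequencies summing to 1.  The analysis
keeps three-event LSVs combining an alternative-exon decision with intron
retention, classifies the two non-IR events by junction span (shorter =
inclusion, longer = skipping), computes PSI and splicing efficiency per LSV,
bins the efficiency by PSI, and tests whether efficiency at intermediate PSI
(40-60%) is lower than at extreme PSI (0-10% and 90-100% combined) using a
bootstrap of the median difference plus a one-sided Wilcoxon signed-rank
test.  A companion routine analyzes binary-event panels (PSI + adjacent
intron PIR across knockdown conditions), where splicing efficiency is
SE = 100 - PIR and coordination shows up as dSE exceedances concentrated at
intermediate dPSI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .core_model import BinnedEfficiencyProfile

logger = logging.getLogger("exondef")

__all__ = [
    "FilterReport",
    "CoordinationStats",
    "read_lsv_table",
    "filter_lsvs",
    "classify_and_quantify",
    "quantify_lsvs",
    "bin_profile",
    "intermediate_vs_extreme_test",
    "kd_coordination",
]

_REQUIRED = ("lsv_id", "junction_start", "junction_end", "is_ir", "frequency")


def read_lsv_table(path) -> pd.DataFrame:
    """Read a MAJIQlopedia-style TSV (one row per junction)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    return table


@dataclass
class FilterReport:
    """Per-filter drop counts from :func:`filter_lsvs`."""

    n_input: int
    dropped: dict[str, int] = field(default_factory=dict)
    n_kept: int = 0


def _junction_distance(group: pd.DataFrame, mode: str) -> float:
    non_ir = group[~group["is_ir"].astype(bool)]
    if len(non_ir) != 2:
        return np.nan
    if mode == "span":
        spans = (non_ir["junction_end"] - non_ir["junction_start"]).to_numpy()
        return float(abs(spans[0] - spans[1]))
    if mode == "ends":
        ends = non_ir["junction_end"].to_numpy()
        return float(abs(ends[0] - ends[1]))
    raise ValueError(f"unknown distance mode {mode!r}")


def filter_lsvs(table: pd.DataFrame, min_reads: int = 0,
                min_junction_distance: float = 300.0,
                min_lowest_two_sum: float = 0.01,
                distance_mode: str = "span"
                ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the LSV quality filters, in order, with per-filter drop counts.

    1. exactly 3 events, at least one IR;
    2. distance between the two non-IR junctions > ``min_junction_distance``
       (excludes alternative 3'/5' splice-site events; ``distance_mode``
       'span' compares junction span lengths, 'ends' the 3' end coordinates);
    3. sum of the two lowest event frequencies >= ``min_lowest_two_sum``;
    4. total junction reads >= ``min_reads`` (when a ``median_count``
       column is present).
    """
    keys = ["lsv_id"] + (["condition"] if "condition" in table.columns else [])
    groups = table.groupby(keys if len(keys) > 1 else keys[0], sort=True)
    report = FilterReport(n_input=groups.ngroups)

    sizes = groups.size()
    n_ir = groups["is_ir"].sum()
    keep = set(sizes[(sizes == 3) & (n_ir >= 1)].index)
    report.dropped["structure"] = report.n_input - len(keep)

    dist = {lsv: _junction_distance(g, distance_mode)
            for lsv, g in groups if lsv in keep}
    kept2 = {lsv for lsv in keep
             if np.isfinite(dist[lsv]) and dist[lsv] > min_junction_distance}
    report.dropped["junction_distance"] = len(keep) - len(kept2)

    lowest2 = {lsv: float(np.sort(g["frequency"].to_numpy())[:2].sum())
               for lsv, g in groups if lsv in kept2}
    kept3 = {lsv for lsv in kept2 if lowest2[lsv] >= min_lowest_two_sum}
    report.dropped["lowest_two_sum"] = len(kept2) - len(kept3)

    if "median_count" in table.columns and min_reads > 0:
        totals = groups["median_count"].sum()
        kept4 = {lsv for lsv in kept3 if totals[lsv] >= min_reads}
    else:
        kept4 = kept3
    report.dropped["read_coverage"] = len(kept3) - len(kept4)

    report.n_kept = len(kept4)
    for name, n in report.dropped.items():
        if n:
            logger.info("filter %s dropped %d LSVs", name, n)
    key_index = pd.MultiIndex.from_frame(table[keys]) if len(keys) > 1 \
        else pd.Index(table["lsv_id"])
    out = table[key_index.isin(kept4)].copy()
    return out, report


def classify_and_quantify(lsv: pd.DataFrame) -> tuple[float, float]:
    """(PSI %, efficiency fraction) of one three-event LSV.

    Of the two non-IR events the shorter junction span is inclusion and the
    longer is skipping; PSI = 100 * incl/(incl+skip), efficiency =
    incl + skip.  Raises on two IR events or tied junction spans.
    """
    is_ir = lsv["is_ir"].astype(bool)
    if int(is_ir.sum()) != 1:
        raise ValueError("LSV must contain exactly one IR event")
    non_ir = lsv[~is_ir]
    spans = (non_ir["junction_end"] - non_ir["junction_start"]).to_numpy()
    if spans[0] == spans[1]:
        raise ValueError("tied junction spans: cannot classify inclusion/skipping")
    freqs = non_ir["frequency"].to_numpy(float)
    incl = freqs[np.argmin(spans)]
    skip = freqs[np.argmax(spans)]
    if incl + skip <= 0:
        raise ValueError("no productive junction reads")
    return 100.0 * incl / (incl + skip), float(incl + skip)


def quantify_lsvs(table: pd.DataFrame) -> pd.DataFrame:
    """PSI/efficiency per LSV (and condition, when present).

    Ambiguous records (two IR events, tied spans, zero productive reads)
    are flagged and excluded, with a count logged.
    """
    keys = ["lsv_id"] + (["condition"] if "condition" in table.columns else [])
    rows, flagged = [], 0
    for key, group in table.groupby(keys, sort=True):
        try:
            psi, eff = classify_and_quantify(group)
        except ValueError:
            flagged += 1
            continue
        key = key if isinstance(key, tuple) else (key,)
        rows.append((*key, psi, eff))
    if flagged:
        logger.info("excluded %d unclassifiable LSVs", flagged)
    return pd.DataFrame(rows, columns=keys + ["psi", "efficiency"])


def bin_profile(events: pd.DataFrame, n_bins: int = 10,
                condition: str = "") -> BinnedEfficiencyProfile:
    """Equal-width PSI binning of quantified events.

    Bins are half-open [lo, hi) with the last bin closed at 100.  Empty bins
    carry NaN medians (missing, not zero).  When the table has a
    ``condition`` column and a label is given, it is filtered first.
    """
    if len(events) == 0:
        raise ValueError("no events to bin")
    if condition and "condition" in events.columns:
        events = events[events["condition"] == condition]
    edges = np.linspace(0.0, 100.0, n_bins + 1)
    psi = events["psi"].to_numpy(float)
    eff = events["efficiency"].to_numpy(float)
    idx = np.minimum(np.digitize(psi, edges[1:-1]), n_bins - 1)
    medians = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            medians[b] = np.median(eff[mask])
    return BinnedEfficiencyProfile(bin_edges=edges, median_efficiency=medians,
                                   counts=counts, condition=condition)


@dataclass
class CoordinationStats:
    """Intermediate-vs-extreme efficiency contrast of one event set."""

    difference: float            # median eff (PSI 40-60) - median eff (extremes)
    ci_low: float
    ci_high: float
    p_value: float               # one-sided bootstrap p, alternative: difference < 0
    wilcoxon_p: float            # one-sided signed-rank across bootstrap replicates
    n_intermediate: int
    n_extreme: int
    n_boot: int
    min_reads: int = 0
    bootstrap_differences: np.ndarray = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def intermediate_vs_extreme_test(events: pd.DataFrame, n_boot: int = 1000,
                                 seed: int = 0, min_reads: int = 0
                                 ) -> CoordinationStats:
    """Bootstrap contrast of median efficiency: PSI 40-60% vs 0-10% + 90-100%.

    Events are resampled with replacement within each PSI group; the
    replicate statistic is the difference of group medians, summarized as a
    point estimate with a 95% percentile CI.  The primary ``p_value`` is an
    exactly calibrated one-sided permutation probability: group labels are
    shuffled ``n_boot`` times and the observed difference compared with the
    permutation distribution (alternative: efficiency genuinely drops at
    intermediate PSI).  ``wilcoxon_p`` additionally reports the one-sided
    Wilcoxon signed-rank statistic over the bootstrap replicates (exact for
    < 25 replicates, normal approximation otherwise); because replicates of
    one dataset are mutually dependent, that variant overstates
    significance and is kept for reference only.  Deterministic under
    ``seed``.
    """
    psi = events["psi"].to_numpy(float)
    eff = events["efficiency"].to_numpy(float)
    mid = eff[(psi >= 40.0) & (psi <= 60.0)]
    ext = eff[(psi <= 10.0) | (psi >= 90.0)]
    if mid.size == 0 or ext.size == 0:
        raise ValueError("empty PSI group: test skipped")
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = (np.median(rng.choice(mid, mid.size, replace=True))
                    - np.median(rng.choice(ext, ext.size, replace=True)))
    diff = float(np.median(mid) - np.median(ext))
    lo, hi = np.percentile(boots, [2.5, 97.5])
    pooled = np.concatenate([mid, ext])
    perm = np.empty(n_boot)
    for b in range(n_boot):
        shuffled = rng.permutation(pooled)
        perm[b] = (np.median(shuffled[:mid.size])
                   - np.median(shuffled[mid.size:]))
    p_boot = (1.0 + float(np.sum(perm <= diff))) / (n_boot + 1.0)
    nonzero = boots[boots != 0]
    if nonzero.size == 0:
        p_w = 1.0
    else:
        method = "exact" if nonzero.size < 25 else "approx"
        p_w = float(wilcoxon(nonzero, alternative="less", method=method).pvalue)
    return CoordinationStats(difference=diff, ci_low=float(lo), ci_high=float(hi),
                             p_value=min(p_boot, 1.0),
                             wilcoxon_p=min(max(p_w, np.nextafter(0, 1)), 1.0),
                             n_intermediate=int(mid.size), n_extreme=int(ext.size),
                             n_boot=n_boot, min_reads=min_reads,
                             bootstrap_differences=boots)


def kd_coordination(binary_table: pd.DataFrame, dse_threshold: float = 5.0,
                    dpsi_bins: np.ndarray | None = None,
                    control_condition: str = "control",
                    subset_sd_threshold: float = 10.0,
                    subset_min_conditions: int = 100) -> dict:
    """Coordination of dPSI and dSE across knockdown conditions.

    For every event and condition, dPSI and dSE (SE = 100 - PIR) are taken
    relative to the control condition; the fraction of observations with
    |dSE| > ``dse_threshold`` is reported per dPSI bin.  Events suitable for
    individual profiling are flagged separately: PSI standard deviation
    above ``subset_sd_threshold`` across conditions and non-zero intron
    retention in more than ``subset_min_conditions`` conditions.
    """
    if control_condition not in set(binary_table["condition"]):
        raise ValueError(f"missing control condition {control_condition!r}")
    if dpsi_bins is None:
        dpsi_bins = np.linspace(-100.0, 100.0, 21)
    t = binary_table.copy()
    t["se"] = 100.0 - t["pir"].astype(float)
    ctrl = t[t["condition"] == control_condition].set_index("event_id")
    kd = t[t["condition"] != control_condition]
    counts_per_event = kd.groupby("event_id").size()
    if (counts_per_event < 1).any():
        raise ValueError("every event needs at least one non-control condition")
    kd = kd.join(ctrl[["psi", "se"]], on="event_id", rsuffix="_ctrl")
    kd = kd.dropna(subset=["psi_ctrl"])
    dpsi = (kd["psi"] - kd["psi_ctrl"]).to_numpy(float)
    dse = (kd["se"] - kd["se_ctrl"]).to_numpy(float)
    exceed = np.abs(dse) > dse_threshold

    n_bins = len(dpsi_bins) - 1
    idx = np.clip(np.digitize(dpsi, dpsi_bins[1:-1]), 0, n_bins - 1)
    frac = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            frac[b] = float(exceed[mask].mean())
    profile = pd.DataFrame({"dpsi_low": dpsi_bins[:-1], "dpsi_high": dpsi_bins[1:],
                            "fraction_dse_exceeding": frac, "n": counts})

    per_event = t.groupby("event_id").agg(
        psi_sd=("psi", "std"),
        n_nonzero_ir=("pir", lambda x: int((x > 0).sum())))
    subset = per_event[(per_event["psi_sd"] > subset_sd_threshold)
                       & (per_event["n_nonzero_ir"] > subset_min_conditions)]
    return {"profile": profile, "subset_event_ids": list(subset.index),
            "dse_threshold": dse_threshold}
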