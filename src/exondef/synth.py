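"""Synthetic-data generation for every pipeline stage.

The generators emulate the statistical structure the analysis assumes, so the
whole pipeline is testable without any external download:

* minigene mutagenesis tables -- steady-state isoform frequencies of a
  ground-truth two-step model, perturbed per mutation by a multiplicative
  fold-change on the assigned exon-definition rate, with replicate noise
  drawn from the scaling-law error model;
* RBP-knockdown panels -- the same minigenes with a regulatory mode
  (flags over k1, k2a, k2b, k3) applied as a common fold-change epsilon;
* three-junction LSV tables for two conditions whose efficiency-PSI relation
  follows the reduced core model (lambda, delta), with junction coordinates
  and negative-binomial read depths;
* binary-event panels (PSI + adjacent-intron PIR) across many knockdown
  conditions with a mixture of coordinated and independent regulation.

Every generator is a pure function of its seed.  Ground truth (parameters,
fold-changes, modes) is returned alongside each dataset for recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_model import CoreModelParams, core_psi_efficiency
from .error_model import FREQ_COLUMNS, ErrorModelParams, replicate_columns
from .fitting import (EXON_RATES, MinigeneAnnotation, MutagenesisDataset,
                      predict_frequencies)
from .kinetics import ISOFORMS, KineticParameters
from .rbp import RegulatoryMode

logger = logging.getLogger("exondef")

__all__ = [
    "SyntheticConfig",
    "default_truth_parameters",
    "generate_minigene_dataset",
    "generate_kd_panel",
    "generate_lsv_tables",
    "generate_binary_event_panel",
]

_F_COLS = [FREQ_COLUMNS[iso] for iso in ISOFORMS]


def default_truth_parameters() -> KineticParameters:
    """Ground-truth two-step parameters with a slow second AE step.

    The second AE definition step is 20x slower than the first
    (k2b/k2a = 0.05), which produces the characteristic splicing-efficiency
    drop at intermediate PSI.  Dissociation rates and synthesis are at the
    fixed values used throughout (0.01/s, 0.001/s).
    """
    return KineticParameters(k1=0.05, k3=0.04, k2a=0.1, k2b=0.005,
                             kspli=0.2, kret=0.003, kincl=0.0015,
                             kskip=0.002, kdr1=0.001, kdr2=0.0012)


@dataclass
class SyntheticConfig:
    """Study conditions for all synthetic generators."""

    truth: KineticParameters = field(default_factory=default_truth_parameters)
    n_mutants: int = 405
    #: fraction of mutants per assigned exon (AE-heavy, as in deep
    #: mutagenesis of a three-exon minigene where the AE carries most
    #: splicing-effective positions: 274 of 405)
    exon_weights: dict = field(default_factory=lambda: {
        "exon1": 0.16, "AE": 0.68, "exon3": 0.16})
    #: sd of the natural log of mutation fold-changes
    fold_sd_log: float = 1.0
    error_model: ErrorModelParams = field(
        default_factory=lambda: ErrorModelParams.uniform(alpha=0.9, b0=0.005))
    n_replicates: int = 3
    noise: bool = True
    annotation: MinigeneAnnotation = field(default_factory=MinigeneAnnotation)
    # LSV / transcriptome generators
    core_normal: CoreModelParams = field(
        default_factory=lambda: CoreModelParams(lam=0.2, delta=0.95))
    core_cancer: CoreModelParams = field(
        default_factory=lambda: CoreModelParams(lam=0.02, delta=0.95))
    n_events: int = 2000
    read_depth: float = 50.0
    contamination: float = 0.0


def _draw_positions(rng: np.random.Generator, cfg: SyntheticConfig) -> tuple[list[int], list[str]]:
    a = cfg.annotation
    bounds = {"exon1": a.exon1, "AE": a.exon2, "exon3": a.exon3}
    exon_names = list(cfg.exon_weights)
    probs = np.array([cfg.exon_weights[e] for e in exon_names], float)
    probs /= probs.sum()
    counts = rng.multinomial(cfg.n_mutants, probs)
    positions, exons = [], []
    for exon, n in zip(exon_names, counts):
        lo, hi = bounds[exon]
        positions.extend(int(p) for p in rng.integers(lo, hi + 1, size=n))
        exons.extend([exon] * n)
    order = rng.permutation(len(positions))
    return [positions[i] for i in order], [exons[i] for i in order]


def _noisy_replicates(rng, means: np.ndarray, em: ErrorModelParams,
                      n_replicates: int) -> np.ndarray:
    """(R, n_rep, 5) clipped-and-renormalized noisy replicate frequencies."""
    R = means.shape[0]
    reps = np.empty((R, n_replicates, 5))
    for j, iso in enumerate(ISOFORMS):
        sd = np.asarray(em.std(iso, means[:, j]))
        reps[:, :, j] = means[:, None, j] + rng.normal(
            0.0, 1.0, size=(R, n_replicates)) * sd[:, None]
    reps = np.clip(reps, 0.0, None)
    sums = reps.sum(axis=2, keepdims=True)
    sums[sums == 0] = 1.0
    reps /= sums
    reorder = (np.argsort(reps.mean(axis=1), axis=1)
               != np.argsort(means, axis=1)).any(axis=1)
    if reorder.any():
        logger.info("noise changed isoform ordering in %d/%d rows",
                    int(reorder.sum()), R)
    return reps


def _dataset_from_means(cfg: SyntheticConfig, rng, means: np.ndarray,
                        positions, exons) -> MutagenesisDataset:
    ids = ["WT"] + [f"mut{j:04d}" for j in range(1, means.shape[0])]
    if cfg.noise:
        reps = _noisy_replicates(rng, means, cfg.error_model, cfg.n_replicates)
        X = reps.mean(axis=1)
    else:
        reps = np.repeat(means[:, None, :], cfg.n_replicates, axis=1)
        X = means.copy()
    tab = pd.DataFrame(X, index=pd.Index(ids, name="minigene_id"), columns=_F_COLS)
    tab.insert(0, "mutation_position",
               [np.nan] + [float(p) for p in positions])
    for j, iso in enumerate(ISOFORMS):
        for r, col in enumerate(replicate_columns(iso, cfg.n_replicates)):
            tab[col] = reps[:, r, j]
    return MutagenesisDataset.from_frequencies(
        tab, cfg.error_model, cfg.annotation, wt_id="WT")


def generate_minigene_dataset(cfg: SyntheticConfig, seed: int
                              ) -> tuple[MutagenesisDataset, dict]:
    """WT + n_mutants records from the ground-truth model.

    Each mutant scales its assigned exon-definition rate(s) by a log-normal
    fold-change (AE mutations scale k2a and k2b by the same factor).
    Replicates are means plus Gaussian noise with the error-model std,
    clipped to [0, 1] and renormalized.  Returns the dataset and the hidden
    truth (parameters, positions, exon assignments, fold-changes, noiseless
    means).
    """
    rng = np.random.default_rng(seed)
    variant = cfg.truth.variant
    positions, exons = _draw_positions(rng, cfg)
    folds = np.exp(rng.normal(0.0, cfg.fold_sd_log, size=cfg.n_mutants))
    all_exons = [""] + exons
    all_folds = np.concatenate([[1.0], folds])
    means = predict_frequencies(variant, cfg.truth, all_exons, all_folds)
    dataset = _dataset_from_means(cfg, rng, means, positions, exons)
    truth = {"params": cfg.truth, "variant": variant, "positions": positions,
             "exons": exons, "fold_changes": pd.Series(folds, index=dataset.mutant_ids),
             "means": means}
    return dataset, truth


def generate_kd_panel(cfg: SyntheticConfig, mode: RegulatoryMode, epsilon: float,
                      seed: int, truth: dict | None = None
                      ) -> tuple[MutagenesisDataset, dict]:
    """Minigene panel under an RBP knockdown with regulatory mode ``mode``.

    Epsilon is applied to the flagged definition rates on top of each
    minigene's mutation fold-change; the noise machinery is shared with the
    control generator.  ``truth`` from :func:`generate_minigene_dataset`
    fixes the mutant panel; otherwise a fresh panel is drawn.
    """
    if cfg.truth.variant == "one_step" and (mode.k2a or mode.k2b):
        raise ValueError("AE-step flags are incompatible with a one-step truth")
    rng = np.random.default_rng(seed)
    if truth is None:
        _, truth = generate_minigene_dataset(cfg, seed)
    kd_params = mode.apply(cfg.truth, epsilon)
    all_exons = [""] + truth["exons"]
    all_folds = np.concatenate([[1.0], truth["fold_changes"].to_numpy()])
    means = predict_frequencies(kd_params.variant, kd_params, all_exons, all_folds)
    dataset = _dataset_from_means(cfg, rng, means, truth["positions"], truth["exons"])
    kd_truth = dict(truth)
    kd_truth.update({"kd_params": kd_params, "mode": mode, "epsilon": epsilon,
                     "means": means})
    return dataset, kd_truth


def generate_lsv_tables(cfg: SyntheticConfig, seed: int,
                        conditions: tuple[str, str] = ("normal", "cancer")
                        ) -> tuple[pd.DataFrame, dict]:
    """Three-junction LSV tables for two conditions with shared lsv_ids.

    Per event a first-step association constant K2a is drawn log-uniformly,
    spanning PSI ~1% to ~99% -- the range that three-event AE-IR LSVs
    surviving the lowest-two-events filter occupy; (PSI, efficiency) follow
    the core model of each condition, and read counts are drawn
    negative-binomially around ``cfg.read_depth``; event frequencies are the
    multinomial junction-read fractions.  A ``cfg.contamination`` fraction of
    events violates the 300-nt junction-distance rule (alternative
    splice-site mimics).
    """
    rng = np.random.default_rng(seed)
    core = {conditions[0]: cfg.core_normal, conditions[1]: cfg.core_cancer}
    n = cfg.n_events
    # u = K2a * sqrt(lambda) is condition-independent; K2a differs via lambda
    log_u = rng.uniform(-1.0, 1.0, size=n)
    incl_span = rng.integers(200, 1001, size=n)
    extra = rng.integers(400, 3001, size=n)
    contaminated = rng.random(n) < cfg.contamination
    extra[contaminated] = rng.integers(10, 251, size=int(contaminated.sum()))
    gene_start = rng.integers(10_000, 1_000_000, size=n)

    rows = []
    for cond in conditions:
        params = core[cond]
        k2a = 10.0 ** log_u / np.sqrt(params.lam)
        psi, eff = core_psi_efficiency(params, k2a)
        probs = np.stack([eff * psi, eff * (1 - psi), 1 - eff], axis=1)
        depth = rng.negative_binomial(10, 10 / (10 + cfg.read_depth), size=n) + 1
        for e in range(n):
            counts = rng.multinomial(depth[e], probs[e])
            freqs = counts / depth[e]
            g = gene_start[e]
            juncs = [
                (g, g + incl_span[e], False, freqs[0], counts[0]),        # inclusion
                (g, g + incl_span[e] + extra[e], False, freqs[1], counts[1]),  # skipping
                (g, g + 1, True, freqs[2], counts[2]),                    # IR
            ]
            for start, end, is_ir, fq, ct in juncs:
                rows.append((f"lsv{e:05d}", f"gene{e:05d}", cond,
                             int(start), int(end), bool(is_ir), fq, int(ct)))
    table = pd.DataFrame(rows, columns=["lsv_id", "gene_id", "condition",
                                        "junction_start", "junction_end",
                                        "is_ir", "frequency", "median_count"])
    truth = {"core": core, "log_u": log_u, "contaminated": contaminated,
             "fold_change": core[conditions[1]].lam / core[conditions[0]].lam}
    return table, truth


def generate_binary_event_panel(cfg: SyntheticConfig, n_events: int,
                                n_conditions: int, seed: int,
                                coordinated_fraction: float = 0.5
                                ) -> tuple[pd.DataFrame, dict]:
    """Binary-event panel (PSI + adjacent-intron PIR) across KD conditions.

    A ``coordinated_fraction`` of events responds to knockdowns through the
    AE recognition strength (moving along the core efficiency-PSI curve,
    i.e. coupled dPSI/dSE); the rest respond through constitutive-exon
    recognition (delta; efficiency changes at fixed PSI) or not at all.
    Condition 'control' is unperturbed.
    """
    if n_conditions < 1:
        raise ValueError("need at least the control condition")
    rng = np.random.default_rng(seed)
    lam = 10.0 ** rng.uniform(-1.0, -0.3, size=n_events)
    delta = rng.uniform(0.9, 0.98, size=n_events)
    log_u0 = rng.uniform(-1.0, 1.0, size=n_events)
    coordinated = rng.random(n_events) < coordinated_fraction
    conditions = ["control"] + [f"kd{c:03d}" for c in range(1, n_conditions)]

    rows = []
    for ci, cond in enumerate(conditions):
        if cond == "control":
            log_u = log_u0
            d = delta
        else:
            shift = rng.normal(0.0, 0.8, size=n_events)
            log_u = np.where(coordinated, log_u0 + shift, log_u0)
            dshift = rng.normal(0.0, 0.02, size=n_events)
            d = np.where(coordinated, delta, np.clip(delta + dshift, 0.5, 1.0))
        u = 10.0 ** log_u
        psi = u ** 2 / (1 + u ** 2)
        k2a = u / np.sqrt(lam)
        eff = d ** 2 * (1 + u ** 2) / (1 + k2a + u ** 2)
        for e in range(n_events):
            rows.append((f"event{e:05d}", cond,
                         100.0 * psi[e], 100.0 * (1.0 - eff[e])))
    table = pd.DataFrame(rows, columns=["event_id", "condition", "psi", "pir"])
    truth = {"lam": lam, "delta": delta, "coordinated": coordinated}
    return table, truth
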