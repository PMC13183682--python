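"""Kinetic models of coupled alternative-exon (AE) and intron-retention (IR) decisions.

The models describe a three-exon minigene whose pre-mRNA is synthesized at a
constant rate and whose exons are recognized ("defined") by the spliceosome via
reversible binding.  Depending on which exons are defined, irreversible splicing
catalysis produces one of five terminal isoforms: AE inclusion, AE skipping,
full intron retention (fullIR), or retention of only the first (1IR) or second
(2IR) intron.  Unspliced species are slowly exported from the nucleus (rate
``kret``) and become IR products; terminal isoforms are degraded with
isoform-specific rates.

Two model variants are provided:

* ``one_step`` -- the AE is defined in a single reversible step (rate ``k2``,
  reverse ``k5``); 17 species.
* ``two_step`` -- AE definition requires two consecutive reversible steps
  (``k2a``/``k5a`` then ``k2b``/``k5b``) through a partially defined
  intermediate that cannot initiate splicing; 21 species.  The intermediate
  acts as a kinetic-proofreading stage: at intermediate AE recognition the
  flux stalls there and exits as fullIR, which couples the AE decision (PSI)
  to overall splicing efficiency.

Because synthesis is constant and every reaction is first order, the ODE
system is affine-linear, ``dx/dt = A x + b``, and the steady state is obtained
by a direct linear solve.  The same reaction list drives an exact stochastic
simulation (Gillespie) for single-cell isoform distributions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

logger = logging.getLogger("exondef")

__all__ = [
    "KineticParameters",
    "IsoformDistribution",
    "ReactionNetwork",
    "SteadyStateError",
    "ISOFORMS",
    "ONE_STEP_SPECIES",
    "TWO_STEP_SPECIES",
    "build_model",
    "steady_state",
    "isoform_frequencies",
    "simulate_ssa",
    "SSAResult",
]

#: Terminal isoforms, in species-vector order.
ISOFORMS = ("inclusion", "skipping", "fullIR", "1IR", "2IR")

# Exon-definition states P<e1>_<ae>_<e3> ('a' = partially defined AE, two-step
# only), partially spliced intermediates (P11_x: intron 1 removed; Px_11:
# intron 2 removed), then the five terminal isoforms.
ONE_STEP_SPECIES = (
    "P0_0_0", "P1_0_0", "P0_1_0", "P0_0_1",
    "P1_1_0", "P1_0_1", "P0_1_1", "P1_1_1",
    "P11_0", "P11_1", "P0_11", "P1_11",
) + ISOFORMS

TWO_STEP_SPECIES = (
    "P0_0_0", "P1_0_0", "P0_a_0", "P0_1_0", "P0_0_1",
    "P1_a_0", "P1_1_0", "P1_0_1", "P0_a_1", "P0_1_1",
    "P1_a_1", "P1_1_1",
    "P11_0", "P11_1", "P0_11", "P1_11",
) + ISOFORMS

_ONE_STEP_RATES = ("s", "k1", "k2", "k3", "k4", "k5", "k6",
                   "kspli", "kret", "kincl", "kskip", "kdr1", "kdr2")
_TWO_STEP_RATES = ("s", "k1", "k2a", "k2b", "k3", "k4", "k5a", "k5b", "k6",
                   "kspli", "kret", "kincl", "kskip", "kdr1", "kdr2")


class SteadyStateError(RuntimeError):
    """The affine-linear system has no unique, finite steady state."""


@dataclass
class KineticParameters:
    """Rate constants of the exon-definition models (all per second).

    ``k2`` is the AE definition rate of the one-step model; ``k2a``/``k2b``
    are the first/second AE definition-step rates of the two-step model.
    Exactly one of the two conventions may be populated.  Dissociation rates
    ``k4``, ``k5`` (``k5a``/``k5b``) and ``k6`` default to the fixed value
    0.01/s and the synthesis rate ``s`` to 0.001/s.
    """

    k1: float = 0.01
    k3: float = 0.01
    k2: float | None = None
    k2a: float | None = None
    k2b: float | None = None
    k4: float = 0.01
    k5: float = 0.01
    k5a: float = 0.01
    k5b: float = 0.01
    k6: float = 0.01
    kspli: float = 0.1
    kret: float = 0.001
    kincl: float = 0.001
    kskip: float = 0.001
    kdr1: float = 0.001
    kdr2: float = 0.001
    s: float = 0.001

    def __post_init__(self) -> None:
        if self.k2 is not None and (self.k2a is not None or self.k2b is not None):
            raise ValueError("populate either k2 (one-step) or k2a/k2b (two-step), not both")
        for name, value in self.as_dict().items():
            if value is not None and value < 0:
                raise ValueError(f"negative rate {name}={value}")

    @property
    def variant(self) -> str:
        if self.k2 is not None:
            return "one_step"
        if self.k2a is not None and self.k2b is not None:
            return "two_step"
        raise ValueError("neither k2 nor (k2a, k2b) populated")

    def as_dict(self) -> dict[str, float | None]:
        return asdict(self)

    def replace(self, **changes) -> "KineticParameters":
        d = self.as_dict()
        d.update(changes)
        return KineticParameters(**d)

    def scaled(self, **factors: float) -> "KineticParameters":
        """Return a copy with the named rates multiplied by the given factors."""
        d = self.as_dict()
        for name, fac in factors.items():
            if d.get(name) is None:
                raise ValueError(f"rate {name} not populated in this variant")
            d[name] = d[name] * fac
        return KineticParameters(**d)

    def to_json(self, path=None) -> str:
        payload = {"variant": self.variant,
                   "rates": {k: v for k, v in self.as_dict().items() if v is not None}}
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "KineticParameters":
        payload = json.loads(source)
        return cls(**payload["rates"])


@dataclass
class IsoformDistribution:
    """Steady-state frequencies of the five terminal isoforms.

    ``psi`` is 100 * inclusion / (inclusion + skipping) in percent (NaN when
    both productive isoforms vanish) and ``efficiency`` is the productive
    fraction inclusion + skipping.
    """

    inclusion: float
    skipping: float
    fullIR: float
    first_ir: float
    second_ir: float

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([self.inclusion, self.skipping, self.fullIR,
                         self.first_ir, self.second_ir])

    @property
    def efficiency(self) -> float:
        return self.inclusion + self.skipping

    @property
    def psi(self) -> float:
        prod = self.inclusion + self.skipping
        if prod <= 0:
            return math.nan
        return 100.0 * self.inclusion / prod

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ISOFORMS, self.frequencies))


@dataclass
class ReactionNetwork:
    """Affine-linear reaction network dx/dt = A x + b.

    ``reactions`` lists (rate_name, rate_value, reactant_index, product_index);
    a ``None`` reactant marks zeroth-order synthesis and a ``None`` product
    marks degradation.
    """

    variant: str
    species: tuple[str, ...]
    reactions: list[tuple[str, float, int | None, int | None]]
    params: KineticParameters
    A: np.ndarray = field(repr=False, default=None)
    b: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n = len(self.species)
        A = np.zeros((n, n))
        b = np.zeros(n)
        for _name, rate, src, dst in self.reactions:
            if src is None:
                b[dst] += rate
            else:
                A[src, src] -= rate
                if dst is not None:
                    A[dst, src] += rate
        self.A, self.b = A, b

    @property
    def isoform_indices(self) -> list[int]:
        return [self.species.index(iso) for iso in ISOFORMS]

    def rhs(self, x: np.ndarray) -> np.ndarray:
        return self.A @ x + self.b

    def relaxation_time(self) -> float:
        """Slowest relaxation timescale, -1/max Re(eigenvalue) of A (seconds)."""
        ev = np.linalg.eigvals(self.A)
        slowest = np.max(ev.real)
        if slowest >= 0:
            raise SteadyStateError("system is not asymptotically stable")
        return -1.0 / slowest


def _chain_reactions(species: Sequence[str], rates: dict[str, float],
                     two_step: bool) -> list[tuple[str, float, int | None, int | None]]:
    idx = {name: i for i, name in enumerate(species)}
    rxn: list[tuple[str, float, int | None, int | None]] = []

    def add(name: str, src: str | None, dst: str | None) -> None:
        rxn.append((name, rates[name], None if src is None else idx[src],
                    None if dst is None else idx[dst]))

    add("s", None, "P0_0_0")

    ae_states = ("0", "a", "1") if two_step else ("0", "1")
    # exon 1 definition/dissociation on every unspliced state and on Px_11
    for ae in ae_states:
        for e3 in ("0", "1"):
            add("k1", f"P0_{ae}_{e3}", f"P1_{ae}_{e3}")
            add("k4", f"P1_{ae}_{e3}", f"P0_{ae}_{e3}")
    add("k1", "P0_11", "P1_11")
    add("k4", "P1_11", "P0_11")
    # exon 3 definition/dissociation, incl. the intron-1-spliced pair P11_x
    for ae in ae_states:
        for e1 in ("0", "1"):
            add("k3", f"P{e1}_{ae}_0", f"P{e1}_{ae}_1")
            add("k6", f"P{e1}_{ae}_1", f"P{e1}_{ae}_0")
    add("k3", "P11_0", "P11_1")
    add("k6", "P11_1", "P11_0")
    # AE definition
    for e1 in ("0", "1"):
        for e3 in ("0", "1"):
            if two_step:
                add("k2a", f"P{e1}_0_{e3}", f"P{e1}_a_{e3}")
                add("k5a", f"P{e1}_a_{e3}", f"P{e1}_0_{e3}")
                add("k2b", f"P{e1}_a_{e3}", f"P{e1}_1_{e3}")
                add("k5b", f"P{e1}_1_{e3}", f"P{e1}_a_{e3}")
            else:
                add("k2", f"P{e1}_0_{e3}", f"P{e1}_1_{e3}")
                add("k5", f"P{e1}_1_{e3}", f"P{e1}_0_{e3}")
    # splicing catalysis: an intron flanked by two defined exons is removed
    add("kspli", "P1_1_0", "P11_0")
    add("kspli", "P1_1_1", "P11_1")
    add("kspli", "P0_1_1", "P0_11")
    add("kspli", "P1_1_1", "P1_11")
    add("kspli", "P1_0_1", "skipping")
    add("kspli", "P11_1", "inclusion")
    add("kspli", "P1_11", "inclusion")
    # nuclear export of unspliced / partially spliced species
    for name in species:
        if name.startswith("P") and "11" not in name:
            add("kret", name, "fullIR")
    add("kret", "P0_11", "1IR")
    add("kret", "P1_11", "1IR")
    add("kret", "P11_0", "2IR")
    add("kret", "P11_1", "2IR")
    # isoform degradation; fullIR degrades at kdr1 + kdr2
    add("kincl", "inclusion", None)
    add("kskip", "skipping", None)
    add("kdr1", "1IR", None)
    add("kdr2", "2IR", None)
    add("kdr1", "fullIR", None)
    add("kdr2", "fullIR", None)
    return rxn


def build_model(variant: str, params: KineticParameters) -> ReactionNetwork:
    """Assemble the reaction network for ``variant`` ('one_step'/'two_step')."""
    if variant == "one_step":
        if params.k2 is None:
            raise ValueError("one_step variant requires k2")
        species = ONE_STEP_SPECIES
        names = _ONE_STEP_RATES
    elif variant == "two_step":
        if params.k2a is None or params.k2b is None:
            raise ValueError("two_step variant requires k2a and k2b")
        species = TWO_STEP_SPECIES
        names = _TWO_STEP_RATES
    else:
        raise ValueError(f"unknown variant {variant!r}")
    rates = {name: getattr(params, name) for name in names}
    reactions = _chain_reactions(species, rates, two_step=(variant == "two_step"))
    return ReactionNetwork(variant=variant, species=species,
                           reactions=reactions, params=params)


def steady_state(model: ReactionNetwork) -> np.ndarray:
    """Unique steady state of the affine-linear system, by direct linear solve.

    Raises :class:`SteadyStateError` when the system is singular (e.g. a
    terminal isoform receives influx but has zero degradation rate).
    """
    try:
        x = np.linalg.solve(-model.A, model.b)
    except np.linalg.LinAlgError as exc:
        raise SteadyStateError("singular system: no steady state") from exc
    resid = np.abs(model.rhs(x)).max()
    if not np.isfinite(x).all() or resid > 1e-10 * max(model.params.s, 1e-300):
        raise SteadyStateError(f"steady-state residual too large ({resid:.3g})")
    return x


def isoform_frequencies(model_or_species, state: np.ndarray) -> IsoformDistribution:
    """Normalize the five terminal-isoform abundances of a species vector."""
    if isinstance(model_or_species, ReactionNetwork):
        species = model_or_species.species
    else:
        species = tuple(model_or_species)
    idx = [species.index(iso) for iso in ISOFORMS]
    abundances = np.asarray(state, dtype=float)[idx]
    total = abundances.sum()
    if total <= 0:
        raise SteadyStateError("all terminal isoform abundances are zero")
    f = abundances / total
    return IsoformDistribution(inclusion=f[0], skipping=f[1], fullIR=f[2],
                               first_ir=f[3], second_ir=f[4])


def steady_state_distribution(model: ReactionNetwork) -> IsoformDistribution:
    """Convenience: steady state followed by isoform normalization."""
    return isoform_frequencies(model, steady_state(model))


def degradation_flux(model: ReactionNetwork, state: np.ndarray) -> float:
    """Total degradation flux out of the system (equals s at steady state)."""
    flux = 0.0
    for _name, rate, src, dst in model.reactions:
        if dst is None:
            flux += rate * state[src]
    return flux


# ---------------------------------------------------------------------------
# Stochastic simulation (exact SSA, vectorized over cells)
# ---------------------------------------------------------------------------

@dataclass
class SSAResult:
    """Ensemble of per-cell molecule counts at ``t_end``.

    ``counts`` has shape (n_cells, n_species).  ``psi`` holds the per-cell
    PSI in percent (NaN for cells without productive isoform molecules).
    """

    species: tuple[str, ...]
    counts: np.ndarray
    t_end: float
    scale: float

    @property
    def isoform_counts(self) -> np.ndarray:
        idx = [self.species.index(iso) for iso in ISOFORMS]
        return self.counts[:, idx]

    @property
    def psi(self) -> np.ndarray:
        iso = self.isoform_counts
        prod = iso[:, 0] + iso[:, 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(prod > 0, 100.0 * iso[:, 0] / np.maximum(prod, 1), np.nan)
        return psi

    def mean_frequencies(self) -> np.ndarray:
        iso = self.isoform_counts.sum(axis=0).astype(float)
        return iso / iso.sum()

    def frequency_standard_errors(self) -> np.ndarray:
        """Monte-Carlo SE of the ensemble-mean isoform frequencies."""
        iso = self.isoform_counts.astype(float)
        totals = iso.sum(axis=1, keepdims=True)
        ok = totals[:, 0] > 0
        freqs = iso[ok] / totals[ok]
        return freqs.std(axis=0, ddof=1) / np.sqrt(ok.sum())

    def psi_mode_count(self, bins: int = 20, min_fraction: float = 0.05) -> int:
        """Number of local maxima of the per-cell PSI histogram.

        A bin is a mode when it exceeds both neighbours and holds at least
        ``min_fraction`` of the cells; 1 indicates a unimodal (gradual)
        splicing response across cells.
        """
        psi = self.psi
        psi = psi[np.isfinite(psi)]
        if psi.size == 0:
            return 0
        hist, _ = np.histogram(psi, bins=bins, range=(0.0, 100.0))
        padded = np.concatenate([[-1], hist, [-1]])
        floor = min_fraction * psi.size
        modes = 0
        i = 1
        while i <= bins:
            j = i
            while j < bins and padded[j + 1] == padded[i]:
                j += 1
            if padded[i] > padded[i - 1] and padded[i] > padded[j + 1] and padded[i] >= floor:
                modes += 1
            i = j + 1
        return modes


def simulate_ssa(model: ReactionNetwork, n_cells: int, t_end: float,
                 seed: int, scale: float | None = None,
                 max_events: int = 2_000_000) -> SSAResult:
    """Exact stochastic simulation (Gillespie) of the reaction network.

    Concentrations are converted to molecule numbers with ``scale``
    (molecules per concentration unit); by default ``scale`` is chosen so the
    deterministic steady state holds ~1000 molecules in total.  All cells
    start empty and are propagated to ``t_end``; the algorithm is exact per
    cell and vectorized across the ensemble.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if model.params.s <= 0:
        raise ValueError("zero total propensity at start: synthesis rate s is zero")
    if scale is None:
        ss = steady_state(model)
        scale = 1000.0 / ss.sum()
    if model.params.s * scale * t_end < 1:
        logger.warning("scale so small that <1 synthesis event is expected")

    rng = np.random.default_rng(seed)
    n_rxn = len(model.reactions)
    n_sp = len(model.species)
    rates = np.array([r[1] for r in model.reactions])
    srcs = np.array([-1 if r[2] is None else r[2] for r in model.reactions])
    dsts = np.array([-1 if r[3] is None else r[3] for r in model.reactions])
    synth = srcs < 0

    counts = np.zeros((n_cells, n_sp), dtype=np.int64)
    t = np.zeros(n_cells)
    active = np.ones(n_cells, dtype=bool)
    events = 0
    while active.any():
        idx = np.flatnonzero(active)
        sub = counts[idx]
        # zeroth-order propensity s*scale; first-order k * reactant count
        prop = np.where(synth[None, :], np.broadcast_to(rates * scale, (idx.size, n_rxn)),
                        rates[None, :] * sub[:, np.clip(srcs, 0, None)])
        total = prop.sum(axis=1)
        alive = total > 0
        if not alive.any():
            break
        idx = idx[alive]
        prop = prop[alive]
        total = total[alive]
        dt = rng.exponential(1.0 / total)
        t_new = t[idx] + dt
        fired = t_new <= t_end
        t[idx] = np.where(fired, t_new, t_end)
        active[idx[~fired]] = False
        idx = idx[fired]
        if idx.size == 0:
            continue
        prop = prop[fired]
        # categorical draw per cell
        u = rng.random(idx.size)[:, None] * prop.sum(axis=1, keepdims=True)
        choice = (prop.cumsum(axis=1) < u).sum(axis=1)
        choice = np.minimum(choice, n_rxn - 1)
        src_sp = srcs[choice]
        dst_sp = dsts[choice]
        has_src = src_sp >= 0
        np.subtract.at(counts, (idx[has_src], src_sp[has_src]), 1)
        has_dst = dst_sp >= 0
        np.add.at(counts, (idx[has_dst], dst_sp[has_dst]), 1)
        events += idx.size
        if events > max_events * max(1, n_cells):
            raise RuntimeError("SSA exceeded the event budget; reduce scale or t_end")
    return SSAResult(species=model.species, counts=counts, t_end=t_end, scale=scale)
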