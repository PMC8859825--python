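"""Interfacial descriptors and validation statistics.

Immersion enthalpy ΔH_imm = (H_slab+liquid − H_slab − H_liquid)/A quantifies
how strongly a crystal facet is wetted by a solvent; the difference of the
water and octanol immersion enthalpies, scaled by RT ln 10, defines the
nanomaterial partitioning descriptor log P^NM (positive ⇒ lipophilic
preference). PMF summaries (well depth E_min, bulk-referenced binding free
energy ΔF_ads), Pearson correlation and affinity rankings support validation
against experimental adsorption data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import constants
from .potentials import SurfacePMFTable, surface_pmf_eval

__all__ = [
    "ImmersionRecord",
    "DescriptorSet",
    "PMFSummary",
    "RankingResult",
    "immersion_enthalpy",
    "log_p_nm",
    "pmf_summary",
    "pearson_r",
    "rank_proteins",
    "block_average_error",
]


@dataclass(frozen=True)
class ImmersionRecord:
    """Immersion enthalpy of a slab–liquid interface, kJ/(mol nm²)."""

    H_slab_liquid: float
    H_slab: float
    H_liquid: float
    area: float
    dH_imm: float
    error: float | None = None


@dataclass(frozen=True)
class DescriptorSet:
    """Facet-level hydrophobicity descriptors."""

    facet: str
    dH_imm_water: float
    dH_imm_octanol: float
    logP_NM: float


@dataclass(frozen=True)
class PMFSummary:
    dF_ads: float  # kT
    E_min: float  # kT
    h_min_location: float  # nm

    @property
    def binding(self) -> bool:
        return self.E_min < 0.0


def block_average_error(series: np.ndarray, plateau_rtol: float = 0.05) -> float:
    """Standard error of the mean of a correlated series by block doubling.

    Blocks are doubled until the error estimate changes by less than
    plateau_rtol over two consecutive doublings (or the block count drops
    below 8), which absorbs the autocorrelation of the underlying trajectory.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for block averaging")
    errors = []
    block = 1
    while x.size // block >= 8:
        n_blocks = x.size // block
        means = x[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
        errors.append(means.std(ddof=1) / math.sqrt(n_blocks))
        if len(errors) >= 3:
            e2, e1, e0 = errors[-3], errors[-2], errors[-1]
            if (
                abs(e0 - e1) <= plateau_rtol * e0
                and abs(e1 - e2) <= plateau_rtol * e0
            ):
                return float(e0)
        block *= 2
    return float(errors[-1])


def _mean_and_error(x) -> tuple[float, float | None]:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.size == 1:
        return float(arr[0]), None
    if arr.size < 100:
        raise ValueError("energy time series must have at least 100 samples")
    return float(arr.mean()), block_average_error(arr)


def immersion_enthalpy(H_slab_liquid, H_slab, H_liquid, area: float) -> ImmersionRecord:
    """Immersion enthalpy (H_sl − H_s − H_l)/A in kJ/(mol nm²).

    Each argument is a mean enthalpy in kJ/mol, or a time series of
    instantaneous enthalpies from which the mean and a block-average standard
    error are computed.
    """
    if area <= 0:
        raise ValueError("interfacial area must be positive")
    msl, esl = _mean_and_error(H_slab_liquid)
    ms, es = _mean_and_error(H_slab)
    ml, el = _mean_and_error(H_liquid)
    dh = (msl - ms - ml) / area
    err = None
    parts = [e for e in (esl, es, el) if e is not None]
    if parts:
        err = math.sqrt(sum(e * e for e in parts)) / area
    return ImmersionRecord(msl, ms, ml, area, dh, err)


def log_p_nm(
    dH_imm_water: float,
    dH_imm_octanol: float,
    temperature: float = 298.15,
) -> float:
    """Nanomaterial octanol–water partitioning descriptor log P^NM.

    (ΔH_imm,water − ΔH_imm,octanol) / (RT ln 10) with the enthalpies in
    kJ/(mol nm²); positive values indicate lipophilic preference (octanol
    wets the facet more exothermically than water).
    """
    rt = constants.R_GAS_KJ * temperature
    return (dH_imm_water - dH_imm_octanol) / (rt * math.log(10.0))


def pmf_summary(table: SurfacePMFTable, n_dense: int = 4001) -> PMFSummary:
    """Well depth and bulk-referenced binding free energy of a PMF profile.

    E_min is the global minimum of the interpolated profile (with its
    location); ΔF_ads = −ln[(1/L) ∫ exp(−F(h)) dh] over the sampled range L,
    i.e. the Boltzmann-weighted depth relative to a flat bulk profile, in kT.
    Requires a zero-referenced table.
    """
    if not table.zero_ref:
        raise ValueError("pmf_summary requires a zero-referenced table")
    lo, hi = table.h_min, table.r_c
    h = np.linspace(lo, hi, n_dense)
    f = np.asarray(surface_pmf_eval(table, h), dtype=float)
    k = int(np.argmin(f))
    e_min, h_loc = float(f[k]), float(h[k])
    if 0 < k < n_dense - 1:  # polish between neighbouring dense nodes
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda x: float(surface_pmf_eval(table, float(x))),
            bounds=(float(h[k - 1]), float(h[k + 1])),
            method="bounded",
        )
        if res.fun < e_min:
            e_min, h_loc = float(res.fun), float(res.x)
    length = hi - lo
    integ = np.trapezoid(np.exp(-np.clip(f, -700, 700)), h)
    df = -math.log(integ / length)
    return PMFSummary(dF_ads=float(df), E_min=e_min, h_min_location=h_loc)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("inputs must have equal length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class RankingResult:
    order: tuple[str, ...]  # most negative energy first
    ranks: dict[str, int]
    has_ties: bool
    n_agree: int | None = None
    kendall_tau: float | None = None


def rank_proteins(
    energies: dict[str, float], reference: list[str] | None = None
) -> RankingResult:
    """Affinity ranking: ascending energy (strongest binder = rank 1).

    Ties are broken lexicographically by id and flagged. If a reference
    ordering is supplied, the count of agreeing positions and the Kendall τ
    between the two orderings are reported.
    """
    if not energies:
        raise ValueError("no energies supplied")
    items = sorted(energies.items(), key=lambda kv: (kv[1], kv[0]))
    order = tuple(k for k, _ in items)
    values = [v for _, v in items]
    has_ties = len(values) != len(set(values))
    ranks = {k: i + 1 for i, k in enumerate(order)}
    n_agree = None
    tau = None
    if reference is not None:
        if set(reference) != set(order):
            raise ValueError("reference ranking must contain the same ids")
        n_agree = sum(1 for a, b in zip(order, reference) if a == b)
        ref_rank = {k: i for i, k in enumerate(reference)}
        if len(order) > 1:
            tau = float(
                stats.kendalltau(
                    [ranks[k] for k in order], [ref_rank[k] + 1 for k in order]
                ).statistic
            )
    return RankingResult(order, ranks, has_ties, n_agree, tau)
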