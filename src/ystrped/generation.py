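"""Average generation time and mutation/meiosis association.

Generation time is estimated as (total father->son birth-interval years) /
(number of meioses with reliable year data), with a bootstrap band obtained
by resampling branches (edges) with replacement.  The association between
documented time depth and observed mutations is quantified by OLS of the
number of mutations (y) on the number of meioses (x), plus Spearman rank
correlation on the same variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import Pedigree


@dataclass
class GenerationTimeEstimate:
    total_years: float
    total_meioses: int
    estimate: float                      # years per meiosis
    ci: tuple[float, float] | None = None
    n_boot: int = 0
    seed: int | None = None


@dataclass
class AssociationResult:
    panel: str
    mode: str
    n_pairs: int
    n_meioses: int
    slope: float
    intercept: float
    p_slope: float
    r2_multiple: float
    r2_adjusted: float
    spearman_rho: float
    spearman_p: float


def _edge_intervals(pedigrees: list[Pedigree]) -> list[float]:
    edges = []
    for ped in pedigrees:
        edges.extend(ped.edge_year_intervals())
    return edges


def average_generation_time(pedigrees: list[Pedigree]) -> GenerationTimeEstimate:
    """Point estimate over all meioses with birth years on both ends."""
    edges = _edge_intervals(pedigrees)
    if not edges:
        raise ValueError("no meioses with usable birth-year data")
    total = float(sum(edges))
    return GenerationTimeEstimate(total, len(edges), total / len(edges))


def bootstrap_generation_ci(pedigrees: list[Pedigree],
                            n_boot: int = 1000,
                            seed: int | None = None) -> GenerationTimeEstimate:
    """Point estimate plus percentile bootstrap band over resampled edges."""
    est = average_generation_time(pedigrees)
    edges = np.array(_edge_intervals(pedigrees), dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, edges.size, size=(n_boot, edges.size))
    means = edges[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return GenerationTimeEstimate(est.total_years, est.total_meioses,
                                  est.estimate, (float(lo), float(hi)),
                                  n_boot, seed)


def regress_mutations_on_meioses(meioses, mutations,
                                 panel: str = "All",
                                 mode: str = "single") -> AssociationResult:
    """OLS of mutations on meioses with intercept, plus Spearman rho.

    ``meioses`` and ``mutations`` are pair-level vectors (one entry per
    genealogical pair; trios contribute all their pairs).
    """
    x = np.asarray(meioses, dtype=float)
    y = np.asarray(mutations, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in meioses")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    rho, sp = spearman_assoc(x, y)
    return AssociationResult(
        panel=panel, mode=mode, n_pairs=int(x.size), n_meioses=int(x.sum()),
        slope=float(model.params[1]), intercept=float(model.params[0]),
        p_slope=float(model.pvalues[1]),
        r2_multiple=float(model.rsquared),
        r2_adjusted=float(model.rsquared_adj),
        spearman_rho=rho, spearman_p=sp)


def spearman_assoc(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; p via t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
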