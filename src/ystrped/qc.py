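"""Non-paternity screening.

Two screens are applied in a fixed order:

(a) *haplogroup concordance* — members of a lineage must share the same
    Y-SNP sub-haplogroup label; a discordant pair is excluded, a trio with
    exactly one discordant member is reduced to the concordant pair;
(b) *iterative Grubbs outlier test* on the per-genealogy mutations/meioses
    ratio — the most extreme genealogy is removed (or, for a trio, reduced
    to its least-mutated pair) while the Grubbs p-value stays below alpha.

A genealogy excluded here never reaches rate estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counting import count_mutations_genealogy
from .registry import PanelRegistry
from .types import Haplotype, Pedigree

RETAINED = "retained"

EXCLUDED_HAPLOGROUP = "excluded_haplogroup"
EXCLUDED_OUTLIER = "excluded_outlier"
REDUCED_TRIO = "reduced_trio"


@dataclass
class QCResult:
    lineage_id: str
    status: str
    detail: str = ""
    grubbs_p: float | None = None


class NotTestable(ValueError):
    """Grubbs test undefined: fewer than 3 values or zero variance."""


def grubbs_statistic(values, alternative: str = "two-sided") -> tuple[float, float]:
    """Grubbs statistic G = max |x - mean| / sd and its p-value.

    ``alternative`` restricts the tested deviation: "max", "min" or
    "two-sided" (most extreme deviation, either direction).  The p-value is
    the classical t-based Grubbs null: with
    t^2 = n(n-2)G^2 / ((n-1)^2 - nG^2), p = c * n * P(T_{n-2} > t), where
    c is 2 for the two-sided alternative and 1 otherwise (capped at 1).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise NotTestable(f"need at least 3 values, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise NotTestable("zero variance")
    mean = x.mean()
    if alternative == "max":
        g = (x.max() - mean) / sd
        sides = 1
    elif alternative == "min":
        g = (mean - x.min()) / sd
        sides = 1
    elif alternative == "two-sided":
        g = np.abs(x - mean).max() / sd
        sides = 2
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    # G is bounded by (n-1)/sqrt(n); at the bound t -> inf, p -> 0.
    denom = (n - 1) ** 2 - n * g ** 2
    if denom <= 0:
        return float(g), 0.0
    t = np.sqrt(n * (n - 2) * g ** 2 / denom)
    p = min(1.0, sides * n * stats.t.sf(t, n - 2))
    return float(g), float(p)


def poisson_deviance_residuals(counts: dict[str, tuple[int, int]]
                               ) -> dict[str, float]:
    """Signed Poisson deviance residuals of per-genealogy mutation counts.

    ``counts`` maps lineage -> (mutations k, meioses m).  Under a common
    per-meiosis rate lambda, k_i ~ Poisson(lambda m_i); the raw ratio k/m
    is heteroscedastic (its variance scales with 1/m) and right-skewed, so
    the normal-theory Grubbs test applied to it is anticonservative.  The
    deviance residual
    r_i = sign(k - mu) sqrt(2 (k log(k/mu) - (k - mu))),  mu = lambda_hat m,
    is approximately standard normal and makes the screen calibrated while
    preserving the outlier signal.
    """
    ks = np.array([k for k, _ in counts.values()], dtype=float)
    ms = np.array([m for _, m in counts.values()], dtype=float)
    lam = ks.sum() / ms.sum()
    mu = lam * ms
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(ks > 0, ks * np.log(ks / mu), 0.0)
    dev = np.sign(ks - mu) * np.sqrt(np.maximum(2 * (term - (ks - mu)), 0.0))
    return dict(zip(counts, dev.tolist()))


def _most_extreme(ratios: dict[str, float]) -> str:
    x = np.array(list(ratios.values()))
    mean = x.mean()
    keys = list(ratios)
    return keys[int(np.argmax(np.abs(x - mean)))]


def iterative_grubbs_screen(ratios: dict[str, float],
                            alpha: float = 0.05,
                            alternative: str = "two-sided") -> list[QCResult]:
    """Remove the most extreme lineage while the Grubbs p-value < alpha.

    Returns one QCResult per input lineage.  With fewer than 3 testable
    values no testing is done and everything is retained with a warning.
    """
    remaining = dict(ratios)
    results: dict[str, QCResult] = {}
    while True:
        if len(remaining) < 3:
            if not results:
                warnings.warn("fewer than 3 genealogies: Grubbs screen skipped")
            break
        try:
            _, p = grubbs_statistic(list(remaining.values()), alternative)
        except NotTestable as err:
            warnings.warn(f"Grubbs screen stopped: {err}")
            break
        if p >= alpha:
            break
        worst = _most_extreme(remaining)
        results[worst] = QCResult(worst, EXCLUDED_OUTLIER,
                                  detail="mutations/meioses outlier", grubbs_p=p)
        del remaining[worst]
    for lineage in ratios:
        results.setdefault(lineage, QCResult(lineage, RETAINED))
    return [results[lineage] for lineage in ratios]


def haplogroup_concordance_screen(groups: dict[str, list[Haplotype]]
                                  ) -> list[QCResult]:
    """Screen lineages (2- or 3-member groups) for haplogroup discordance.

    A discordant pair is excluded; a trio with exactly one discordant
    member is reduced to the concordant pair (the discordant sample is
    named in ``detail``); a trio with three distinct labels is excluded.
    Samples without a haplogroup label are skipped with a warning.
    """
    results = []
    for lineage, members in groups.items():
        labelled = [h for h in members if h.haplogroup]
        for hap in members:
            if not hap.haplogroup:
                warnings.warn(f"sample {hap.sample_id}: no haplogroup label, skipped")
        labels = [h.haplogroup for h in labelled]
        if len(set(labels)) <= 1:
            results.append(QCResult(lineage, RETAINED))
        elif len(labelled) == 3 and len(set(labels)) == 2:
            # exactly one discordant member
            odd = next(h for h in labelled
                       if labels.count(h.haplogroup) == 1)
            results.append(QCResult(lineage, REDUCED_TRIO, detail=odd.sample_id))
        else:
            results.append(QCResult(lineage, EXCLUDED_HAPLOGROUP,
                                    detail="/".join(sorted(set(labels)))))
    return results


def _trio_best_pair(ped: Pedigree, haplotypes: dict[str, Haplotype],
                    registry: PanelRegistry, panel: str, mode: str
                    ) -> tuple[str, float]:
    """Find the trio member whose removal leaves the least-mutated pair.

    Returns (removed_sample_id, ratio_of_remaining_pair).
    """
    nodes = ped.sampled_nodes()
    best = None
    for drop in nodes:
        keep = [m for m in nodes if m != drop]
        sub = Pedigree(ped.lineage_id, dict(ped.father), dict(ped.birth_year),
                       {m: ped.sample_of[m] for m in keep})
        count = count_mutations_genealogy(sub, haplotypes, registry, panel)
        ratio = count.total(mode) / count.meioses
        if best is None or ratio < best[1]:
            best = (ped.sample_of[drop], ratio)
    return best


def screen_cohort(pedigrees: list[Pedigree],
                  haplotypes: dict[str, Haplotype],
                  registry: PanelRegistry,
                  alpha: float = 0.05,
                  panel: str = "All",
                  mode: str = "multi",
                  statistic: str = "deviance") -> tuple[list[QCResult], list[Pedigree]]:
    """Full QC: haplogroup screen first, iterative Grubbs screen second.

    The Grubbs screen tests the per-genealogy mutations-versus-meioses
    signal; by default it is applied to Poisson deviance residuals
    (``statistic="deviance"``, see :func:`poisson_deviance_residuals`),
    with the raw mutations/meioses ratio available as
    ``statistic="ratio"``.  When the screen flags a trio, the trio is
    reduced to its least-mutated concordant pair instead of being dropped
    (status ``reduced_trio``); flagged pairs are excluded.  Returns the
    per-lineage QC results and the retained (possibly reduced) pedigrees.
    """
    by_sample = dict(haplotypes)
    groups = {
        ped.lineage_id: [by_sample[s] for s in ped.sampled_leaves
                         if s in by_sample]
        for ped in pedigrees
    }
    hg_results = {r.lineage_id: r for r in haplogroup_concordance_screen(groups)}

    retained: dict[str, Pedigree] = {}
    results: dict[str, QCResult] = {}
    for ped in pedigrees:
        res = hg_results[ped.lineage_id]
        results[ped.lineage_id] = res
        if res.status == EXCLUDED_HAPLOGROUP:
            continue
        if res.status == REDUCED_TRIO:
            keep = {m: s for m, s in ped.sample_of.items() if s != res.detail}
            ped = Pedigree(ped.lineage_id, dict(ped.father),
                           dict(ped.birth_year), keep)
        retained[ped.lineage_id] = ped

    # Iterative Grubbs on the mutations-vs-meioses signal of the survivors.
    while len(retained) >= 3:
        km = {}
        for lineage, ped in retained.items():
            count = count_mutations_genealogy(ped, by_sample, registry, panel)
            km[lineage] = (count.total(mode), count.meioses)
        if statistic == "deviance":
            ratios = poisson_deviance_residuals(km)
        elif statistic == "ratio":
            ratios = {lin: k / m for lin, (k, m) in km.items()}
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        try:
            _, p = grubbs_statistic(list(ratios.values()))
        except NotTestable:
            break
        if p >= alpha:
            break
        worst = _most_extreme(ratios)
        ped = retained[worst]
        if len(ped.sampled_nodes()) == 3:
            removed, _ = _trio_best_pair(ped, by_sample, registry, panel, mode)
            keep = {m: s for m, s in ped.sample_of.items() if s != removed}
            retained[worst] = Pedigree(ped.lineage_id, dict(ped.father),
                                       dict(ped.birth_year), keep)
            results[worst] = QCResult(worst, REDUCED_TRIO, detail=removed,
                                      grubbs_p=p)
        else:
            del retained[worst]
            results[worst] = QCResult(worst, EXCLUDED_OUTLIER,
                                      detail="mutations/meioses outlier",
                                      grubbs_p=p)
    order = [p.lineage_id for p in pedigrees]
    return ([results[lin] for lin in order],
            [retained[lin] for lin in order if lin in retained])
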