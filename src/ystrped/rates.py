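"""Mutation-rate estimation by direct counting.

Rates are the exact ratio (observed mutations) / (meioses), per locus and
per meiosis, in both counting modes.  95% bands are the 2.5% and 97.5%
quantiles of Binomial(n = meioses, p = k/n) divided by n — a quantile band
at the point estimate, undefined when k = 0 (reported as a dash).  Panel
rates pool counts across the panel's loci (sum k / sum n).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats

from .counting import GenealogyCount
from .registry import PanelRegistry
from .types import GenealogyPair

#: Meiosis-depth bins used for the diachronic (saturation) analysis.
DEFAULT_BINS = (("7-10", 7, 10), ("11-19", 11, 19), (">19", 20, None))


class UndefinedRate(ValueError):
    pass


@dataclass
class RateEstimate:
    """Point rate with its binomial-quantile band (None when k = 0)."""

    k: int
    n: int
    rate: float
    ci: tuple[float, float] | None


@dataclass
class LocusMutationStats:
    """Per-locus counts and rates in both counting modes."""

    locus: str
    mutations_single: int
    mutations_multi: int
    meioses: int
    single: RateEstimate = None
    multi: RateEstimate = None

    def __post_init__(self):
        if self.single is None:
            self.single = estimate(self.mutations_single, self.meioses)
        if self.multi is None:
            self.multi = estimate(self.mutations_multi, self.meioses)


def point_rate(k: int, n: int) -> float:
    """Exact mutation rate k/n per locus per meiosis."""
    if n <= 0:
        raise UndefinedRate("zero meioses")
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    return k / n


def binomial_quantile_ci(k: int, n: int) -> tuple[float, float] | None:
    """(Q(0.025)/n, Q(0.975)/n) for Binomial(n, k/n); None when k = 0."""
    p = point_rate(k, n)
    if k == 0:
        return None
    lo = stats.binom.ppf(0.025, n, p) / n
    hi = stats.binom.ppf(0.975, n, p) / n
    return float(lo), float(hi)


def estimate(k: int, n: int) -> RateEstimate:
    return RateEstimate(k, n, point_rate(k, n), binomial_quantile_ci(k, n))


def pool_panel_stats(stats_by_locus: dict[str, LocusMutationStats],
                     panel_loci: list[str],
                     label: str = "panel") -> LocusMutationStats:
    """Pooled panel rate: sum of mutations over sum of meioses."""
    missing = [loc for loc in panel_loci if loc not in stats_by_locus]
    if missing:
        raise KeyError(f"no stats for panel loci: {missing}")
    ks = sum(stats_by_locus[l].mutations_single for l in panel_loci)
    km = sum(stats_by_locus[l].mutations_multi for l in panel_loci)
    n = sum(stats_by_locus[l].meioses for l in panel_loci)
    return LocusMutationStats(label, ks, km, n)


def cohort_locus_stats(counts: list[GenealogyCount],
                       registry: PanelRegistry) -> dict[str, LocusMutationStats]:
    """Aggregate genealogy-level counts into per-locus stats.

    A genealogy contributes its tree meioses to every locus it was counted
    at; loci it excluded (ambiguous) contribute neither mutations nor
    meioses there.
    """
    out = {}
    for locus in registry.panel_loci("All"):
        ks = km = n = 0
        for gc in counts:
            if locus in gc.excluded_loci:
                continue
            if locus in gc.events_single or locus in gc.events_multi:
                ks += gc.events_single.get(locus, 0)
                km += gc.events_multi.get(locus, 0)
                n += gc.meioses
        if n > 0:
            out[locus] = LocusMutationStats(locus, ks, km, n)
    return out


def bin_rates(pairs: list[GenealogyPair],
              pair_counts: dict[tuple[str, str], dict[str, int]],
              mode: str = "single",
              bins=DEFAULT_BINS) -> pd.DataFrame:
    """Pooled rates per meiosis-depth bin.

    ``pair_counts`` maps (sample_a, sample_b) -> per-locus event counts for
    the requested mode summed over the panel of interest.  Genealogies with
    more than two members enter through all their pairs.  Empty bins are
    reported with zero meioses and no rate.
    """
    rows = []
    for label, lo, hi in bins:
        k = n = npairs = 0
        for pair in pairs:
            if pair.meioses < lo or (hi is not None and pair.meioses > hi):
                continue
            counts = pair_counts.get((pair.sample_a, pair.sample_b))
            if counts is None:
                continue
            k += sum(counts.values())
            n += pair.meioses
            npairs += 1
        if n > 0:
            est = estimate(k, n)
            rows.append({"bin": label, "n_pairs": npairs, "mutations": k,
                         "meioses": n, "rate": est.rate,
                         "ci_low": est.ci[0] if est.ci else None,
                         "ci_high": est.ci[1] if est.ci else None})
        else:
            rows.append({"bin": label, "n_pairs": 0, "mutations": 0,
                         "meioses": 0, "rate": None, "ci_low": None,
                         "ci_high": None})
    return pd.DataFrame(rows)


def fisher_compare(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p comparing two mutation/meiosis counts."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def binomial_enrichment_test(k: int, n: int, p0: float,
                             alternative: str = "two-sided") -> float:
    """Exact binomial test of k successes in n at null proportion p0."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)


def round_half_up(x: float, digits: int = 2) -> float:
    """Decimal half-up rounding used for report tables (x1000 scale)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def rates_table(stats_by_locus: dict[str, LocusMutationStats],
                registry: PanelRegistry,
                panels=("Yf", "PP", "YfP", "L", "RM", "All")) -> pd.DataFrame:
    """Report table mirroring the standard locus/panel layout: counts plus
    rates and bands on the x1000 scale, 2 decimals, dash-free (None)."""
    def row(stats: LocusMutationStats, panels_label: str) -> dict:
        def fmt(est: RateEstimate):
            if est.k == 0:
                return None, None, None
            return (round_half_up(est.rate * 1000),
                    round_half_up(est.ci[0] * 1000),
                    round_half_up(est.ci[1] * 1000))
        vs, ls, hs = fmt(stats.single)
        vm, lm, hm = fmt(stats.multi)
        return {"locus": stats.locus, "panels": panels_label,
                "k_single": stats.mutations_single,
                "k_multi": stats.mutations_multi, "meioses": stats.meioses,
                "val_single": vs, "ci_low_single": ls, "ci_high_single": hs,
                "val_multi": vm, "ci_low_multi": lm, "ci_high_multi": hm}

    rows = []
    for locus, stats_ in stats_by_locus.items():
        labels = "/".join(sorted(registry[locus].panels)) if locus in registry else ""
        rows.append(row(stats_, labels))
    for panel in panels:
        loci = [l for l in registry.panel_loci(panel) if l in stats_by_locus]
        if loci:
            rows.append(row(pool_panel_stats(stats_by_locus, loci, panel), panel))
    return pd.DataFrame(rows)
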