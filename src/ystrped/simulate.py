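"""Synthetic cohorts of deep-rooting paternal genealogies.

The generator emulates the sampling design the analysis assumes: documented
lineages of two (occasionally three) living namesakes separated by at least
seven meioses, Y-STR profiles evolved down every father->son edge as
independent per-locus Poisson mutation processes (mostly single-step, with
occasional genuine multi-step jumps), birth years drawn from a
generation-time distribution, and optional injected non-paternity events
(an unrelated haplotype substituted for one sampled member, usually with a
discordant haplogroup label).

Mutations are placed per meiosis, not per pair path, so that pseudo
multi-step changes (two stacked single steps) and trio parsimony counting
arise naturally.  Absolute founder allele values never influence the
downstream statistics — only differences do.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference
from .registry import (DYS389_DERIVED, DYS389_I, DYS389_II, PanelRegistry,
                       default_registry)
from .types import Haplotype, Pedigree, ValidationError

_HAPLOGROUPS = ("R-M269>U152", "R-M269>L2", "R-M269>L23", "E-V13",
                "G-L497", "J-M410", "T-M70", "I-M253")


@dataclass
class SimulationConfig:
    """Generative parameters; defaults follow the reference study cohort."""

    n_lineages: int = 66
    trio_fraction: float = 3 / 66
    meioses_min: int = 7
    meioses_max: int = 30
    locus_rates: dict[str, float] = field(
        default_factory=lambda: reference.locus_rates("single"))
    single_step_prob: float = 0.96
    #: step sizes of genuine multi-step events and their share of the
    #: multi-step mass
    step_sizes: tuple = ((2, 0.75), (3, 0.15), (4, 0.10))
    generation_mean: float = 33.57
    generation_sd: float = 5.0
    generation_bounds: tuple[float, float] = (16.0, 60.0)
    nonpaternity_prob: float = 0.0
    discordant_label_prob: float = 7 / 8
    founder_range: tuple[int, int] = (10, 20)
    haplogroup_pool: tuple = _HAPLOGROUPS
    root_year: float = 1700.0
    seed: int | None = None

    def validate(self) -> None:
        probs = [self.trio_fraction, self.single_step_prob,
                 self.nonpaternity_prob, self.discordant_label_prob]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        if any(r < 0 for r in self.locus_rates.values()):
            raise ValidationError("mutation rates must be non-negative")
        if self.meioses_min < 7:
            raise ValidationError("pairs must be separated by >= 7 meioses")
        if self.meioses_max < self.meioses_min:
            raise ValidationError("meioses_max < meioses_min")
        if abs(sum(w for _, w in self.step_sizes) - 1) > 1e-9:
            raise ValidationError("step-size weights must sum to 1")


@dataclass
class Cohort:
    """A simulated dataset plus its generative truth."""

    haplotypes: list[Haplotype]
    pedigrees: list[Pedigree]
    truth: pd.DataFrame            # one row per lineage
    events: pd.DataFrame           # one row per mutation event
    config: SimulationConfig

    def haplotypes_by_sample(self) -> dict[str, Haplotype]:
        return {h.sample_id: h for h in self.haplotypes}

    def write(self, outdir) -> None:
        from pathlib import Path

        from .io import write_haplotype_table, write_pedigree_file
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_haplotype_table(self.haplotypes, outdir / "haplotypes.tsv",
                              default_registry())
        write_pedigree_file(self.pedigrees, outdir / "pedigree.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.events.to_csv(outdir / "events.tsv", sep="\t", index=False)


def _sim_loci(registry: PanelRegistry, rates: dict[str, float]):
    """Loci evolved by the simulator: every counted locus with a rate.

    DYS389II is emitted, not evolved (it is DYS389I + DYS389II-I)."""
    return [(name, registry[name].copy_count) for name in registry.panel_loci("All")
            if name in rates]


def _draw_founder(rng, loci, lo, hi) -> dict[str, tuple]:
    return {name: tuple(sorted(int(a) for a in rng.integers(lo, hi + 1, copies)))
            for name, copies in loci}


def _step(rng, cfg: SimulationConfig) -> int:
    """Signed repeat change of one mutation event."""
    sign = -1 if rng.random() < 0.5 else 1
    if rng.random() < cfg.single_step_prob:
        return sign
    sizes, weights = zip(*cfg.step_sizes)
    return sign * int(rng.choice(sizes, p=weights))


def _emit(hap_alleles: dict[str, tuple]) -> dict[str, tuple]:
    """Typed profile: raw DYS389II = DYS389I + DYS389II-I."""
    out = dict(hap_alleles)
    if DYS389_I in out and DYS389_DERIVED in out:
        out[DYS389_II] = (out[DYS389_I][0] + out.pop(DYS389_DERIVED)[0],)
    return out


def _branch_depths(rng, cfg, trio: bool):
    m = int(rng.integers(cfg.meioses_min, cfg.meioses_max + 1))
    if not trio:
        return {"a": m // 2, "b": m - m // 2}
    b1 = int(rng.integers(4, 13))
    b2 = int(rng.integers(4, 13))
    c = int(rng.integers(1, 5))
    a_min = max(4, cfg.meioses_min - c - min(b1, b2))
    a = int(rng.integers(a_min, a_min + 9))
    return {"a": a, "c": c, "b1": b1, "b2": b2}


def simulate_dataset(config: SimulationConfig | None = None,
                     registry: PanelRegistry | None = None) -> Cohort:
    """Generate a cohort under the configured mutation and pedigree model.

    Deterministic for a fixed ``config.seed``: identical configs give
    byte-identical output files.
    """
    cfg = config or SimulationConfig()
    cfg.validate()
    registry = registry or default_registry()
    rng = np.random.default_rng(cfg.seed)
    loci = _sim_loci(registry, cfg.locus_rates)
    n_trios = int(round(cfg.n_lineages * cfg.trio_fraction))

    haplotypes: list[Haplotype] = []
    pedigrees: list[Pedigree] = []
    truth_rows, event_rows = [], []
    for idx in range(cfg.n_lineages):
        lin = f"L{idx + 1:03d}"
        trio = idx < n_trios
        depths = _branch_depths(rng, cfg, trio)
        ped = Pedigree(lin)
        founder = _draw_founder(rng, loci, *cfg.founder_range)
        haplogroup = str(rng.choice(cfg.haplogroup_pool))
        root = f"{lin}.R"
        ped.birth_year[root] = cfg.root_year + float(rng.integers(0, 40))
        states = {root: founder}
        n_events = n_single = total_steps = 0

        def grow(branch: str, start: str, depth: int) -> str:
            nonlocal n_events, n_single, total_steps
            node = start
            for i in range(depth):
                child = f"{lin}.{branch}{i + 1}"
                ped.father[child] = node
                interval = float(np.clip(
                    rng.normal(cfg.generation_mean, cfg.generation_sd),
                    *cfg.generation_bounds))
                ped.birth_year[child] = ped.birth_year[node] + interval
                alleles = dict(states[node])
                for name, copies in loci:
                    hits = rng.poisson(cfg.locus_rates[name])
                    for _ in range(hits):
                        step = _step(rng, cfg)
                        vals = list(alleles[name])
                        c = int(rng.integers(0, copies))
                        vals[c] += step
                        alleles[name] = tuple(sorted(vals))
                        n_events += 1
                        n_single += int(abs(step) == 1)
                        total_steps += abs(step)
                        event_rows.append({"lineage_id": lin, "node": child,
                                           "locus": name, "step": step})
                states[child] = alleles
                node = child
            return node

        if trio:
            leaf_a = grow("a", root, depths["a"])
            inner = grow("c", root, depths["c"])
            leaf_b = grow("b", inner, depths["b1"])
            leaf_c = grow("d", inner, depths["b2"])
            leaves = [leaf_a, leaf_b, leaf_c]
        else:
            leaves = [grow("a", root, depths["a"]),
                      grow("b", root, depths["b"])]
        for j, leaf in enumerate(leaves):
            sid = f"{lin}.S{j + 1}"
            ped.sample_of[leaf] = sid
            haplotypes.append(Haplotype(sid, lin, haplogroup,
                                        _emit(states[leaf])))
        pedigrees.append(ped)
        truth_rows.append({
            "lineage_id": lin, "n_sampled": len(leaves),
            "tree_meioses": ped.tree_meioses(),
            "pair_meioses": ped.pairs()[0].meioses,
            "n_events": n_events, "n_single_step": n_single,
            "total_steps": total_steps, "nonpaternity": False,
            "discordant_label": False, "replaced_sample": "",
        })

    cohort = Cohort(haplotypes, pedigrees, pd.DataFrame(truth_rows),
                    pd.DataFrame(event_rows,
                                 columns=["lineage_id", "node", "locus", "step"]),
                    cfg)
    if cfg.nonpaternity_prob > 0:
        flags = rng.random(cfg.n_lineages) < cfg.nonpaternity_prob
        targets = [ped.lineage_id
                   for ped, f in zip(cohort.pedigrees, flags) if f]
        inject_nonpaternity(cohort, rng, targets)
    return cohort


def inject_nonpaternity(cohort: Cohort, rng,
                        lineages: list[str],
                        discordant: dict[str, bool] | None = None) -> None:
    """Replace one sampled haplotype per listed lineage with an unrelated
    founder draw; the haplogroup label is additionally made discordant with
    the configured probability (or as dictated by ``discordant``).

    Mutates the cohort in place and records the event in the truth table.
    """
    cfg = cohort.config
    registry = default_registry()
    loci = _sim_loci(registry, cfg.locus_rates)
    by_sample = cohort.haplotypes_by_sample()
    truth = cohort.truth.set_index("lineage_id")
    for lin in lineages:
        ped = next(p for p in cohort.pedigrees if p.lineage_id == lin)
        victim = str(rng.choice(ped.sampled_leaves))
        hap = by_sample[victim]
        hap.alleles = _emit(_draw_founder(rng, loci, *cfg.founder_range))
        if discordant is not None:
            make_discordant = discordant[lin]
        else:
            make_discordant = bool(rng.random() < cfg.discordant_label_prob)
        if make_discordant:
            others = [g for g in cfg.haplogroup_pool if g != hap.haplogroup]
            hap.haplogroup = str(rng.choice(others))
        truth.loc[lin, ["nonpaternity", "discordant_label",
                        "replaced_sample"]] = [True, make_discordant, victim]
    cohort.truth = truth.reset_index()


def default_qc_cohort(seed: int | None = 0) -> Cohort:
    """The reference screening scenario: 66 lineages (3 trios), seven
    haplogroup-discordant pairs, one haplogroup-discordant trio member and
    one same-label unrelated trio member (a pure mutations/meioses outlier).
    """
    cfg = SimulationConfig(seed=seed)
    cohort = simulate_dataset(cfg)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    trios = [p.lineage_id for p in cohort.pedigrees
             if len(p.sampled_leaves) == 3]
    pairs = [p.lineage_id for p in cohort.pedigrees
             if len(p.sampled_leaves) == 2]
    chosen_pairs = list(rng.choice(pairs, size=7, replace=False))
    targets = chosen_pairs + trios[:2]
    discordant = {lin: True for lin in chosen_pairs}
    discordant[trios[0]] = True    # haplogroup-discordant trio member
    discordant[trios[1]] = False   # silent outlier, caught by Grubbs
    inject_nonpaternity(cohort, rng, targets, discordant)
    return cohort


def truth_recovery_report(cohort: Cohort,
                          stats_by_locus: dict | None = None,
                          qc_results: list | None = None,
                          estimates: list | None = None) -> dict:
    """Compare pipeline outputs against the generative truth.

    Returns a dict with per-locus rate errors and CI-covers-truth flags
    (when rate stats are given), non-paternity sensitivity/specificity
    (when QC results are given) and TMRCA truth coverage (when estimates
    are given).
    """
    report: dict = {}
    if stats_by_locus is not None:
        rows = []
        for locus, st in stats_by_locus.items():
            true_rate = cohort.config.locus_rates.get(locus)
            if true_rate is None:
                continue
            ci = st.multi.ci
            rows.append({
                "locus": locus, "true_rate": true_rate,
                "estimated_rate": st.multi.rate,
                "abs_error": abs(st.multi.rate - true_rate),
                "ci_covers_truth": (ci is not None
                                    and ci[0] <= true_rate <= ci[1]),
            })
        report["rates"] = pd.DataFrame(rows)
    if qc_results is not None:
        from .qc import RETAINED
        truth = cohort.truth.set_index("lineage_id")["nonpaternity"]
        tp = fp = tn = fn = 0
        for res in qc_results:
            positive = res.status != RETAINED
            if truth.get(res.lineage_id, False):
                tp += positive
                fn += not positive
            else:
                fp += positive
                tn += not positive
        report["nonpaternity"] = {
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        }
    if estimates is not None:
        from .tmrca import coverage_fraction
        report["tmrca_coverage_pct"] = coverage_fraction(estimates)
    return report
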