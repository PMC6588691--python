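"""End-to-end pipeline: QC -> counting -> rates -> generation time ->
association -> TMRCA, with all tables written as delimited text."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ysio
from .counting import count_mutations_genealogy, count_mutations_pair
from .generation import bootstrap_generation_ci, regress_mutations_on_meioses
from .qc import screen_cohort
from .rates import bin_rates, cohort_locus_stats, rates_table
from .registry import PanelRegistry, default_registry
from .simulate import SimulationConfig, simulate_dataset
from .tmrca import (compute_posterior, flag_nonpaternity_tmrca,
                    observation_from_pair, pool_mu, summarize_posterior)

log = logging.getLogger("ystrped")


class ConfigurationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Run configuration for the full pipeline.

    Either ``haplotype_table`` + ``pedigree_file`` or ``simulate=True``
    must be provided.
    """

    outdir: str = "ystrped-out"
    haplotype_table: str | None = None
    pedigree_file: str | None = None
    registry_file: str | None = None
    simulate: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    panels: tuple = ("Yf", "PP", "YfP", "L", "RM", "All")
    modes: tuple = ("single", "multi")
    models: tuple = ("IAM", "SMM")
    tmrca_panels: tuple = ("RM", "L", "All")
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("simulation", None)
        cfg = cls(**doc)
        if sim:
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis and write report tables under ``outdir``.

    Returns the report tables keyed by name.  Every exclusion is logged
    with its reason.
    """
    if not config.simulate and not (config.haplotype_table
                                    and config.pedigree_file):
        raise ConfigurationError(
            "no haplotype source: set simulate=true or provide "
            "haplotype_table and pedigree_file")
    bad = [p for p in config.panels if p not in
           ("Yf", "PP", "YfP", "L", "RM", "All")]
    if bad:
        raise ConfigurationError(f"unknown panels: {bad}")

    registry = (PanelRegistry.from_yaml(config.registry_file)
                if config.registry_file else default_registry())
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim_cfg = config.simulation
        if config.seed is not None:
            sim_cfg = dataclasses.replace(sim_cfg, seed=config.seed)
        cohort = simulate_dataset(sim_cfg, registry)
        cohort.write(outdir / "simulated")
        haplotypes, pedigrees = cohort.haplotypes, cohort.pedigrees
    else:
        haplotypes = ysio.read_haplotype_table(config.haplotype_table, registry)
        pedigrees = ysio.read_pedigree_file(config.pedigree_file)

    by_sample = {h.sample_id: h for h in haplotypes}
    tables: dict[str, pd.DataFrame] = {}

    # -- QC ---------------------------------------------------------------
    qc_results, retained = screen_cohort(pedigrees, by_sample, registry,
                                         alpha=config.alpha)
    for res in qc_results:
        if res.status != "retained":
            log.info("QC %s: %s (%s)", res.lineage_id, res.status, res.detail)
    tables["qc"] = pd.DataFrame(
        [{"lineage_id": r.lineage_id, "status": r.status, "detail": r.detail,
          "grubbs_p": r.grubbs_p} for r in qc_results])

    # -- counting + rates -------------------------------------------------
    counts = [count_mutations_genealogy(p, by_sample, registry)
              for p in retained]
    for gc in counts:
        for locus, reason in gc.excluded_loci.items():
            log.info("lineage %s: locus %s excluded (%s)",
                     gc.lineage_id, locus, reason)
    stats = cohort_locus_stats(counts, registry)
    tables["rates"] = rates_table(stats, registry, panels=config.panels)

    # -- pair-level data for bins / association / TMRCA -------------------
    pairs, pair_obs = [], {}
    for ped in retained:
        for pair in ped.pairs():
            pairs.append(pair)
            pair_obs[(pair.sample_a, pair.sample_b)] = count_mutations_pair(
                by_sample[pair.sample_a], by_sample[pair.sample_b], registry)

    bin_frames = []
    for panel in config.panels:
        panel_loci = set(registry.panel_loci(panel))
        for mode in config.modes:
            attr = "events_single" if mode == "single" else "events_multi"
            pc = {key: {o.locus: getattr(o, attr) for o in obs
                        if not o.ambiguous and o.locus in panel_loci}
                  for key, obs in pair_obs.items()}
            frame = bin_rates(pairs, pc, mode)
            frame.insert(0, "panel", panel)
            frame.insert(1, "mode", mode)
            bin_frames.append(frame)
    tables["bins"] = pd.concat(bin_frames, ignore_index=True)

    # -- generation time --------------------------------------------------
    gt = bootstrap_generation_ci(retained, n_boot=config.n_boot,
                                 seed=config.seed)
    tables["gentime"] = pd.DataFrame([{
        "total_years": gt.total_years, "total_meioses": gt.total_meioses,
        "years_per_meiosis": gt.estimate,
        "ci_low": gt.ci[0], "ci_high": gt.ci[1], "n_boot": gt.n_boot}])

    # -- association ------------------------------------------------------
    assoc_rows = []
    for panel in config.panels:
        panel_loci = set(registry.panel_loci(panel))
        for mode in config.modes:
            attr = "events_single" if mode == "single" else "events_multi"
            x = [p.meioses for p in pairs]
            y = [sum(getattr(o, attr)
                     for o in pair_obs[(p.sample_a, p.sample_b)]
                     if not o.ambiguous and o.locus in panel_loci)
                 for p in pairs]
            try:
                assoc_rows.append(dataclasses.asdict(
                    regress_mutations_on_meioses(x, y, panel, mode)))
            except ValueError as err:
                log.warning("association %s/%s skipped: %s", panel, mode, err)
    tables["association"] = pd.DataFrame(assoc_rows)

    # -- TMRCA ------------------------------------------------------------
    tmrca_rows = []
    for panel in config.tmrca_panels:
        panel_loci = set(registry.panel_loci(panel))
        mu = pool_mu(stats, registry.panel_loci(panel))
        for model in config.models:
            for pair in pairs:
                obs = [o for o in pair_obs[(pair.sample_a, pair.sample_b)]
                       if o.locus in panel_loci]
                tobs = observation_from_pair(
                    f"{pair.sample_a}|{pair.sample_b}", panel, obs, mu)
                post = compute_posterior(tobs, model=model)
                est = summarize_posterior(
                    post, tobs.pair_id,
                    observed=pair.observed_tmrca_generations)
                tmrca_rows.append({
                    "pair": tobs.pair_id, "panel": panel, "model": model,
                    "mean": est.mean, "median": est.median, "mode": est.mode,
                    "ci_low": est.ci[0], "ci_high": est.ci[1],
                    "observed": est.observed, "within_ci": est.within_ci,
                    "flagged": flag_nonpaternity_tmrca(est)})
    tables["tmrca"] = pd.DataFrame(tmrca_rows)

    for name, frame in tables.items():
        frame.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    return tables
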