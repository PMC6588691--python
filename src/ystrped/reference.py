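"""Published reference counts from the Northern-Italian deep-rooting
pedigree study whose marker set this package implements.

The study screened 66 documented paternal lineages (63 pairs, 3 trios) down
to 59 genealogies, totalling 718 meioses and 248 observed mutations (229 of
them single-step).  Locus-level mutation/meiosis counts — augmented for some
markers with previously published lineages from the same region — are
shipped as package data and serve both as the default per-locus mutation
rates of the simulator and as worked inputs for the rate machinery.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

# Cohort-level printed totals (inputs, not results).
TOTAL_MEIOSES = 718            # meioses in the 59 retained genealogies
TOTAL_MUTATIONS = 248          # multi-mode mutation events among them
SINGLE_STEP_MUTATIONS = 229    # events of exactly one repeat unit
GENTIME_MEIOSES = 692          # meioses with reliable father birth years
GENTIME_YEARS = 23230          # summed father->son birth intervals
N_LINEAGES = 66
N_TRIOS = 3
RETAINED_GENEALOGIES = 59


def _load(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("ystrped").joinpath(f"data/{name}")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def locus_counts() -> pd.DataFrame:
    """Per-locus published counts: panels, copies, k (both modes), meioses,
    and the published rate/CI columns on the x1000 scale."""
    return _load("locus_counts.csv")


def panel_counts() -> pd.DataFrame:
    """Published panel-pooled counts and rate/CI columns (x1000 scale)."""
    return _load("panel_counts.csv")


def locus_rates(mode: str = "single") -> dict[str, float]:
    """Per-locus per-meiosis rates k/n from the published counts."""
    if mode not in ("single", "multi"):
        raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")
    table = locus_counts()
    return {row["locus"]: row[f"k_{mode}"] / row["meioses"]
            for _, row in table.iterrows()}
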