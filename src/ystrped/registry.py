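"""Locus and panel registry.

The built-in registry covers the 47-marker set analysed in the reference
genealogy study: the Yfiler (Yf), PowerPlex Y23 (PP) and Yfiler Plus (YfP)
commercial panels, the Rapidly Mutating (RM) set and the Leuven in-house
panel (L), plus the catch-all "All" set.  Multi-copy markers (DYS385a/b,
DYS459a/b, DYS724a/b, DYS464a-d, YCAIIa/b, DYF387S1, DYF399S1, DYF403S1a,
DYF404S1) are registered as single loci with copy_count > 1.

DYS389II is typed but never counted directly: mutations at the DYS389
complex are attributed via the derived marker DYS389II-I (DYS389II minus
DYS389I) to avoid double counting, so DYS389II-I is the registry member of
the analysis panels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .types import ValidationError

PANEL_LABELS = ("Yf", "PP", "YfP", "RM", "L", "All")

#: The raw typed marker replaced by a derived one in every analysis panel.
DYS389_I = "DYS389I"
DYS389_II = "DYS389II"
DYS389_DERIVED = "DYS389II-I"


@dataclass(frozen=True)
class Locus:
    name: str
    copy_count: int = 1
    panels: frozenset[str] = field(default_factory=frozenset)
    is_derived: bool = False

    def __post_init__(self) -> None:
        if self.copy_count < 1:
            raise ValidationError(f"{self.name}: copy_count must be >= 1")
        bad = set(self.panels) - set(PANEL_LABELS)
        if bad:
            raise ValidationError(f"{self.name}: unknown panel labels {sorted(bad)}")


class PanelRegistry:
    """Mapping of locus name -> :class:`Locus` with panel views."""

    def __init__(self, loci: list[Locus]):
        self._loci: dict[str, Locus] = {}
        for locus in loci:
            if locus.name in self._loci:
                raise ValidationError(f"duplicate locus {locus.name!r}")
            self._loci[locus.name] = locus

    def __contains__(self, name: str) -> bool:
        return name in self._loci

    def __getitem__(self, name: str) -> Locus:
        return self._loci[name]

    def __iter__(self):
        return iter(self._loci.values())

    @property
    def names(self) -> list[str]:
        return list(self._loci)

    def panel_loci(self, label: str) -> list[str]:
        """Counted loci of a panel, in registry order.

        ``"All"`` is the union of every panel.  The raw DYS389II marker is
        excluded from every analysis panel (its derived counterpart carries
        the counts).
        """
        if label not in PANEL_LABELS:
            raise ValidationError(f"unknown panel {label!r}")
        out = []
        for locus in self._loci.values():
            if locus.name == DYS389_II:
                continue
            if label == "All" or label in locus.panels:
                out.append(locus.name)
        return out

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            locus.name: {
                "copies": locus.copy_count,
                "panels": sorted(locus.panels),
                "derived": locus.is_derived,
            }
            for locus in self
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PanelRegistry":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        loci = [
            Locus(name,
                  copy_count=int(spec.get("copies", 1)),
                  panels=frozenset(spec.get("panels", [])),
                  is_derived=bool(spec.get("derived", False)))
            for name, spec in doc.items()
        ]
        return cls(loci)


def _reference_table() -> pd.DataFrame:
    ref = importlib.resources.files("ystrped").joinpath("data/locus_counts.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def default_registry() -> PanelRegistry:
    """The 47-locus registry of the reference study (plus raw DYS389II)."""
    table = _reference_table()
    loci = []
    for _, row in table.iterrows():
        panels = frozenset(str(row["panels"]).split("/"))
        loci.append(Locus(row["locus"], copy_count=int(row["copies"]),
                          panels=panels,
                          is_derived=row["locus"] == DYS389_DERIVED))
        if row["locus"] == DYS389_I:
            # Raw DYS389II is typed alongside DYS389I but carries no counts.
            loci.append(Locus(DYS389_II, copy_count=1, panels=panels))
    return PanelRegistry(loci)
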