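"""Mutation counting between related haplotypes.

Mutations are counted by direct comparison of the two (or three) haplotypes
of a genealogy, without inferring ancestral states or mutation direction.
Two counting modes are maintained throughout:

``single``
    every allele difference at a locus is one event, regardless of its size
    (a multi-step change counts once);
``multi``
    a difference of d repeat units counts as d independent single-step
    events.

Multi-copy loci are treated as one locus: the two allele multisets are
matched by the bijection minimising the total absolute step difference.
If no bijection assignment is unambiguous (unequal copy numbers, or
minimising bijections that disagree on the event count), the locus is
excluded for that genealogy rather than guessed at.

The DYS389 complex is handled by replacing DYS389II with the derived marker
DYS389II-I = DYS389II - DYS389I before counting, so that a mutation in the
DYS389I stretch is not counted twice.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .registry import (DYS389_DERIVED, DYS389_I, DYS389_II, PanelRegistry)
from .types import Haplotype, Pedigree

_FRAC_TOL = 1e-6


@dataclass
class PairLocusObservation:
    """Per-locus mutation observation for one compared pair."""

    locus: str
    step_difference: int = 0       # signed for single-copy; min total steps for multi-copy
    events_single: int = 0         # 1 if any difference else 0
    events_multi: int = 0          # total absolute steps
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not self.ambiguous:
            assert self.events_multi >= self.events_single >= 0


@dataclass
class GenealogyCount:
    """Per-genealogy mutation counts in both modes.

    ``meioses`` is the tree total (spanning meioses) used for rate
    estimation; pair-path meioses live on the GenealogyPair objects.
    """

    lineage_id: str
    meioses: int
    events_single: dict[str, int] = field(default_factory=dict)
    events_multi: dict[str, int] = field(default_factory=dict)
    excluded_loci: dict[str, str] = field(default_factory=dict)  # locus -> reason

    def total(self, mode: str = "multi") -> int:
        d = self.events_single if mode == "single" else self.events_multi
        return sum(d.values())


class AmbiguousComparison(Exception):
    """Internal marker: the locus comparison has no unambiguous count."""


def step_difference(a1: float, a2: float) -> int:
    """Signed repeat-unit difference a2 - a1.

    Raises :class:`AmbiguousComparison` when the alleles' fractional parts
    differ (incommensurable intermediate alleles, e.g. 13.2 vs 14).
    """
    diff = a2 - a1
    steps = round(diff)
    if abs(diff - steps) > _FRAC_TOL:
        raise AmbiguousComparison(f"incommensurable alleles {a1} vs {a2}")
    return steps


def multicopy_difference(m1, m2) -> tuple[int, int, bool]:
    """Minimal-step matching of two allele multisets.

    Returns ``(min_total_steps, events, ambiguous)``.  All bijections
    between the copies are enumerated (copy number <= 4, so at most 24);
    among those minimising the total absolute step difference, the event
    count (copies with a nonzero step) must be unique — otherwise, or when
    the multisets have different sizes, the comparison is ambiguous.
    """
    m1, m2 = sorted(m1), sorted(m2)
    if len(m1) != len(m2):
        return 0, 0, True
    best_total = None
    event_counts: set[int] = set()
    for perm in itertools.permutations(m2):
        try:
            steps = [abs(step_difference(a, b)) for a, b in zip(m1, perm)]
        except AmbiguousComparison:
            continue
        total = sum(steps)
        events = sum(1 for s in steps if s)
        if best_total is None or total < best_total:
            best_total, event_counts = total, {events}
        elif total == best_total:
            event_counts.add(events)
    if best_total is None or len(event_counts) != 1:
        return 0, 0, True
    return best_total, event_counts.pop(), False


def derive_dys389(haplotype: Haplotype) -> Haplotype:
    """Replace DYS389II with the derived DYS389II-I marker.

    If either DYS389 marker is missing, both are dropped for this sample
    (the subtraction is undefined).
    """
    hap = haplotype.copy()
    a1, a2 = hap.alleles.get(DYS389_I), hap.alleles.get(DYS389_II)
    hap.alleles.pop(DYS389_II, None)
    hap.alleles.pop(DYS389_DERIVED, None)
    if a1 is None or a2 is None:
        hap.alleles.pop(DYS389_I, None)
        return hap
    hap.alleles[DYS389_DERIVED] = (a2[0] - a1[0],)
    return hap


def _compare_locus(locus: str, a: tuple, b: tuple) -> PairLocusObservation:
    if len(a) == 1 and len(b) == 1:
        try:
            d = step_difference(a[0], b[0])
        except AmbiguousComparison:
            return PairLocusObservation(locus, ambiguous=True)
        return PairLocusObservation(locus, step_difference=d,
                                    events_single=int(d != 0),
                                    events_multi=abs(d))
    total, events, ambiguous = multicopy_difference(a, b)
    if ambiguous:
        return PairLocusObservation(locus, ambiguous=True)
    # Each mutated copy is one single-mode event however many steps it spans.
    return PairLocusObservation(locus, step_difference=total,
                                events_single=events,
                                events_multi=total)


def count_mutations_pair(h1: Haplotype, h2: Haplotype,
                         registry: PanelRegistry,
                         panel: str = "All") -> list[PairLocusObservation]:
    """One observation per panel locus; loci missing in either haplotype
    are skipped, ambiguous comparisons flagged and left uncounted.

    Note the single-mode count at a multi-copy locus is the number of
    mutated copies under the minimal matching (each copy's change is one
    event however many steps it spans).
    """
    h1, h2 = derive_dys389(h1), derive_dys389(h2)
    out = []
    for locus in registry.panel_loci(panel):
        a, b = h1.get(locus), h2.get(locus)
        if a is None or b is None:
            continue
        out.append(_compare_locus(locus, a, b))
    return out


def _single_copy_trio_parsimony(alleles: list[float]) -> tuple[int, int]:
    """Minimal mutation counts for a single-copy locus on a 3-leaf tree.

    ``alleles`` are the leaf states ordered (outgroup, in1, in2) on the
    topology (root -> outgroup, root -> inner -> {in1, in2}); integer
    ancestral states for root and inner node are enumerated on the observed
    allele range.  Returns (single_events, multi_steps): multi = minimal
    total steps; single = minimal number of mutated branches among the
    step-minimising assignments.
    """
    base = alleles[0] - round(alleles[0])
    offsets = [round(a - base) for a in alleles]
    lo, hi = min(offsets), max(offsets)
    best_total, best_branches = None, None
    for root in range(lo, hi + 1):
        for inner in range(lo, hi + 1):
            branch = [abs(offsets[0] - root), abs(inner - root),
                      abs(offsets[1] - inner), abs(offsets[2] - inner)]
            total = sum(branch)
            nonzero = sum(1 for s in branch if s)
            if best_total is None or (total, nonzero) < (best_total, best_branches):
                best_total, best_branches = total, nonzero
    return best_branches, best_total


def count_mutations_genealogy(pedigree: Pedigree,
                              haplotypes: dict[str, Haplotype],
                              registry: PanelRegistry,
                              panel: str = "All") -> GenealogyCount:
    """Genealogy-level counts: pairs by direct comparison, trios by
    parsimony on the documented 3-leaf topology.

    For trios, multi-copy loci are handled by enumerating the observed
    multisets as candidate ancestral states (mutations are rare on this
    time scale); a locus whose pairwise comparisons are ambiguous is
    excluded for the whole genealogy.
    """
    nodes = pedigree.sampled_nodes()
    count = GenealogyCount(pedigree.lineage_id, pedigree.tree_meioses())
    if len(nodes) == 2:
        h1 = haplotypes[pedigree.sample_of[nodes[0]]]
        h2 = haplotypes[pedigree.sample_of[nodes[1]]]
        for obs in count_mutations_pair(h1, h2, registry, panel):
            if obs.ambiguous:
                count.excluded_loci[obs.locus] = "ambiguous comparison"
            else:
                count.events_single[obs.locus] = obs.events_single
                count.events_multi[obs.locus] = obs.events_multi
        return count
    if len(nodes) != 3:
        raise ValueError(
            f"lineage {pedigree.lineage_id}: expected 2 or 3 sampled members, "
            f"got {len(nodes)}")

    # Identify the topological outgroup: the sampled node whose pairwise
    # MRCA with the others is shallowest (= the trio MRCA).
    top = pedigree.mrca(pedigree.mrca(nodes[0], nodes[1]), nodes[2])
    outgroup = None
    for node in nodes:
        others = [m for m in nodes if m != node]
        if pedigree.mrca(*others) != top:
            outgroup = node
            break
    if outgroup is None:
        # Star topology: all three coalesce at the same ancestor; any
        # ordering is equivalent for parsimony.
        outgroup = nodes[0]
    inner = [m for m in nodes if m != outgroup]
    ordered = [outgroup] + inner
    haps = [derive_dys389(haplotypes[pedigree.sample_of[m]]) for m in ordered]

    for locus in registry.panel_loci(panel):
        alleles = [h.get(locus) for h in haps]
        if any(a is None for a in alleles):
            continue
        if all(len(a) == 1 for a in alleles):
            try:
                # Incommensurable fractional parts surface via pairwise checks.
                step_difference(alleles[0][0], alleles[1][0])
                step_difference(alleles[0][0], alleles[2][0])
            except AmbiguousComparison:
                count.excluded_loci[locus] = "ambiguous comparison"
                continue
            single, multi = _single_copy_trio_parsimony([a[0] for a in alleles])
        else:
            single, multi, ambiguous = _multicopy_trio_parsimony(alleles)
            if ambiguous:
                count.excluded_loci[locus] = "ambiguous comparison"
                continue
        count.events_single[locus] = single
        count.events_multi[locus] = multi
    return count


def _multicopy_trio_parsimony(alleles) -> tuple[int, int, bool]:
    """Parsimony for a multi-copy locus on the 3-leaf topology, with the
    observed multisets as ancestral candidates for root and inner node."""
    dist: dict[tuple[int, int], tuple[int, int]] = {}
    for i, j in itertools.combinations_with_replacement(range(3), 2):
        total, events, ambiguous = multicopy_difference(alleles[i], alleles[j])
        if ambiguous:
            return 0, 0, True
        dist[(i, j)] = dist[(j, i)] = (total, events)
    best = None
    for root in range(3):
        for inner in range(3):
            pairs = [(0, root), (root, inner), (inner, 1), (inner, 2)]
            total = sum(dist[p][0] for p in pairs)
            events = sum(dist[p][1] for p in pairs)
            if best is None or (total, events) < best:
                best = (total, events)
    return best[1], best[0], False
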