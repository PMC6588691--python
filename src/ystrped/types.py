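"""Core domain types for pedigree-based Y-STR analysis.

A *haplotype* is one man's multi-locus Y-STR profile (repeat counts, with
multi-copy loci stored as multisets) plus his Y-SNP haplogroup label.  A
*pedigree* is a rooted paternal tree for one documented lineage; every
father->son edge is one meiosis.  A *genealogy pair* is two sampled men of a
lineage together with the documented number of meioses separating them along
the path through their most recent common ancestor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


class ValidationError(ValueError):
    """Raised when an input file or object violates a structural invariant."""


#: Alleles are repeat counts; intermediate alleles (e.g. 13.2) are admitted,
#: so a multiset of alleles is stored as a sorted tuple of floats.
Alleles = tuple[float, ...]


@dataclass
class Haplotype:
    """Multi-locus Y-STR profile of one sampled man.

    Parameters
    ----------
    sample_id, lineage_id : str
        Unique sample label and the paternal lineage it belongs to.
    haplogroup : str
        Y-SNP (sub-)haplogroup label, possibly hierarchical
        (e.g. ``"R-M269>U152"``).  Consumed as an opaque string.
    alleles : dict
        Locus name -> sorted tuple of repeat counts.  Multiset size equals
        the observed copy number; absent loci are simply missing keys.
    """

    sample_id: str
    lineage_id: str
    haplogroup: str
    alleles: dict[str, Alleles] = field(default_factory=dict)

    def get(self, locus: str) -> Alleles | None:
        return self.alleles.get(locus)

    def copy(self) -> "Haplotype":
        return Haplotype(self.sample_id, self.lineage_id, self.haplogroup,
                         dict(self.alleles))


@dataclass
class GenealogyPair:
    """Two sampled men and the documented meioses separating them.

    ``meioses`` is the total number of meiotic events on the path
    a -> MRCA -> b; the observed TMRCA in generations is exactly half of it.
    """

    lineage_id: str
    sample_a: str
    sample_b: str
    meioses: int

    def __post_init__(self) -> None:
        if self.meioses < 1:
            raise ValidationError(
                f"pair ({self.sample_a}, {self.sample_b}): meioses must be >= 1")

    @property
    def observed_tmrca_generations(self) -> float:
        return self.meioses / 2


@dataclass
class Pedigree:
    """Rooted paternal tree of one lineage.

    The tree is stored as a child -> father map.  Node birth years are
    optional; sampled leaves carry sample ids.
    """

    lineage_id: str
    father: dict[str, str] = field(default_factory=dict)
    birth_year: dict[str, float] = field(default_factory=dict)
    sample_of: dict[str, str] = field(default_factory=dict)  # node -> sample_id

    # -- structure ---------------------------------------------------------

    def nodes(self) -> set[str]:
        return set(self.father) | set(self.father.values())

    @property
    def root(self) -> str:
        roots = self.nodes() - set(self.father)
        if len(roots) != 1:
            raise ValidationError(
                f"lineage {self.lineage_id}: expected a single founder, "
                f"found {sorted(roots)}")
        return next(iter(roots))

    def validate(self) -> None:
        """Check connectivity and acyclicity; raise ValidationError."""
        root = self.root  # also checks single-root
        for node in self.father:
            seen = {node}
            cur = node
            while cur in self.father:
                cur = self.father[cur]
                if cur in seen:
                    raise ValidationError(
                        f"lineage {self.lineage_id}: cycle through node {cur!r}")
                seen.add(cur)
            if cur != root:
                raise ValidationError(
                    f"lineage {self.lineage_id}: node {node!r} not connected "
                    f"to founder {root!r}")

    def sampled_nodes(self) -> list[str]:
        return sorted(self.sample_of)

    @property
    def sampled_leaves(self) -> list[str]:
        return sorted(self.sample_of.values())

    # -- meiosis accounting ------------------------------------------------

    def _ancestor_path(self, node: str) -> list[str]:
        path = [node]
        while node in self.father:
            node = self.father[node]
            path.append(node)
        return path

    def path_meioses(self, node_a: str, node_b: str) -> int:
        """Meioses on the path a -> MRCA -> b (one per edge)."""
        pa = self._ancestor_path(node_a)
        pb = set(self._ancestor_path(node_b))
        for i, anc in enumerate(pa):
            if anc in pb:
                j = self._ancestor_path(node_b).index(anc)
                return i + j
        raise ValidationError(
            f"lineage {self.lineage_id}: {node_a!r} and {node_b!r} share no ancestor")

    def mrca(self, node_a: str, node_b: str) -> str:
        pa = self._ancestor_path(node_a)
        pb = set(self._ancestor_path(node_b))
        for anc in pa:
            if anc in pb:
                return anc
        raise ValidationError(f"no common ancestor of {node_a!r}, {node_b!r}")

    def spanning_edges(self) -> list[tuple[str, str]]:
        """Father->son edges of the minimal subtree spanning the sampled nodes.

        These are the meioses a genealogy contributes to rate estimation:
        for a pair they coincide with the connecting path, for a trio they
        form the Steiner tree through the trio's common ancestors (shared
        edges counted once).
        """
        nodes = self.sampled_nodes()
        if not nodes:
            return []
        # MRCA of all sampled nodes = shallowest pairwise MRCA.
        top = nodes[0]
        for other in nodes[1:]:
            top = self.mrca(top, other)
        edges: set[tuple[str, str]] = set()
        for node in nodes:
            cur = node
            while cur != top:
                dad = self.father[cur]
                edges.add((dad, cur))
                cur = dad
        return sorted(edges)

    def tree_meioses(self) -> int:
        """Total meioses spanned by the sampled members (pair: path total)."""
        return len(self.spanning_edges())

    def pairs(self) -> list[GenealogyPair]:
        """All sampled pairs with per-path meioses (trios decomposed)."""
        out = []
        for na, nb in itertools.combinations(self.sampled_nodes(), 2):
            out.append(GenealogyPair(self.lineage_id,
                                     self.sample_of[na], self.sample_of[nb],
                                     self.path_meioses(na, nb)))
        return out

    def edge_year_intervals(self) -> list[float]:
        """Father-to-son birth intervals (years) for spanned meioses with
        birth years on both ends of the edge."""
        out = []
        for dad, son in self.spanning_edges():
            yd, ys = self.birth_year.get(dad), self.birth_year.get(son)
            if yd is not None and ys is not None:
                out.append(ys - yd)
        return out
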