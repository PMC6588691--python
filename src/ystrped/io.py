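"""Readers and writers for haplotype tables, pedigree edge lists and panel
registries.

Haplotype table: delimited text (tab or comma, auto-detected), header row
``sample_id, lineage_id, haplogroup, <locus>, <locus>, ...``; multi-copy
alleles comma-separated within a cell (quote the cell in CSV); empty cell =
locus not typed.

Pedigree edge list: one father->son edge per row,
``lineage_id, father, son, son_birth_year, sample_id`` (the last two may be
empty).  A row with an empty ``father`` declares the founder's birth year /
sample attachment without adding an edge.
"""

from __future__ import annotations

import csv
import warnings

from .registry import PanelRegistry
from .types import Haplotype, Pedigree, ValidationError

_META_COLUMNS = ("sample_id", "lineage_id", "haplogroup")


class ParseError(ValueError):
    """Malformed cell or row in a delimited input file."""


def _sniff_delimiter(path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _parse_alleles(cell: str, row: int, column: str):
    values = []
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise ParseError(
                f"row {row}, column {column!r}: cannot parse allele {token!r}"
            ) from None
    return tuple(sorted(values))


def read_haplotype_table(path, registry: PanelRegistry) -> list[Haplotype]:
    """Read and validate a haplotype table.

    Unknown locus columns are reported with a warning and kept out of the
    haplotypes; duplicate sample ids raise :class:`ValidationError`.
    """
    delim = _sniff_delimiter(path)
    haplotypes: list[Haplotype] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        loci = [c for c in reader.fieldnames or [] if c not in _META_COLUMNS]
        unknown = [c for c in loci if c not in registry]
        if unknown:
            warnings.warn(f"unknown locus columns ignored: {unknown}")
            loci = [c for c in loci if c in registry]
        for i, row in enumerate(reader, start=2):
            sid = (row.get("sample_id") or "").strip()
            if not sid:
                raise ParseError(f"row {i}: missing sample_id")
            if sid in seen:
                raise ValidationError(f"duplicate sample_id {sid!r}")
            seen.add(sid)
            alleles = {}
            for locus in loci:
                cell = (row.get(locus) or "").strip()
                if not cell:
                    continue  # missing, not zero
                parsed = _parse_alleles(cell, i, locus)
                if parsed:
                    if not 1 <= len(parsed) <= 4:
                        raise ValidationError(
                            f"row {i}, column {locus!r}: {len(parsed)} alleles "
                            f"(expected 1-4)")
                    alleles[locus] = parsed
            haplotypes.append(Haplotype(sid, (row.get("lineage_id") or "").strip(),
                                        (row.get("haplogroup") or "").strip(),
                                        alleles))
    return haplotypes


def write_haplotype_table(haplotypes, path, registry: PanelRegistry) -> None:
    loci = [n for n in registry.names]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(list(_META_COLUMNS) + loci)
        for hap in haplotypes:
            row = [hap.sample_id, hap.lineage_id, hap.haplogroup]
            for locus in loci:
                alleles = hap.get(locus)
                row.append("" if alleles is None else
                           ",".join(_format_allele(a) for a in alleles))
            writer.writerow(row)


def _format_allele(a: float) -> str:
    return str(int(a)) if float(a).is_integer() else f"{a:g}"


def read_pedigree_file(path) -> list[Pedigree]:
    """Read pedigrees from an edge-list file and validate each tree.

    Cycles and disconnected nodes raise :class:`ValidationError`; sampled
    pairs closer than 7 meioses are kept but flagged with a warning.
    """
    delim = _sniff_delimiter(path)
    peds: dict[str, Pedigree] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        for i, row in enumerate(reader, start=2):
            lin = (row.get("lineage_id") or "").strip()
            if not lin:
                raise ParseError(f"row {i}: missing lineage_id")
            ped = peds.setdefault(lin, Pedigree(lin))
            father = (row.get("father") or "").strip()
            son = (row.get("son") or "").strip()
            if not son:
                raise ParseError(f"row {i}: missing son node")
            if father:
                if son in ped.father:
                    raise ValidationError(
                        f"row {i}: node {son!r} already has a father")
                ped.father[son] = father
            year = (row.get("son_birth_year") or "").strip()
            if year:
                try:
                    ped.birth_year[son] = float(year)
                except ValueError:
                    raise ParseError(
                        f"row {i}, column 'son_birth_year': bad value {year!r}"
                    ) from None
            sample = (row.get("sample_id") or "").strip()
            if sample:
                ped.sample_of[son] = sample
    for ped in peds.values():
        ped.validate()
        for pair in ped.pairs():
            if pair.meioses < 7:
                warnings.warn(
                    f"lineage {ped.lineage_id}: pair ({pair.sample_a}, "
                    f"{pair.sample_b}) separated by only {pair.meioses} meioses")
    return list(peds.values())


def write_pedigree_file(pedigrees, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["lineage_id", "father", "son", "son_birth_year",
                         "sample_id"])
        for ped in pedigrees:
            root = ped.root
            writer.writerow([ped.lineage_id, "", root,
                             _year(ped, root), ped.sample_of.get(root, "")])
            for son in sorted(ped.father):
                writer.writerow([ped.lineage_id, ped.father[son], son,
                                 _year(ped, son), ped.sample_of.get(son, "")])


def _year(ped: Pedigree, node: str) -> str:
    y = ped.birth_year.get(node)
    return "" if y is None else f"{y:g}"
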