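"""Variant-list ingestion into gene-level binary indicators.

Accepts standard VCF 4.x (via cyvcf2) or the 5/6-column ANNOVAR-style
tabular dialect (chrom, start, end, ref, alt[, gene]; 1-based inclusive).
Records are mapped to genes either through their own gene annotation or a
user-supplied gene-interval table (BED input, 0-based half-open, converted
to 1-based inclusive internally). Two indicator modes exist:

* ``variation`` — every qualifying variant in a gene sets its indicator;
* ``mutation`` — variants found in a SNP exclusion list (e.g. a dbSNP
  extract, supplied as rsIDs or chrom/pos/ref/alt keys) are filtered out
  first, so the mutation vector is element-wise ≤ the variation vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .core_data import DataError, ParseError

_ALLELE_CHARS = set("ACGTN-")


@dataclass(frozen=True)
class VariantRecord:
    """One normalized variant call (1-based position, single alt allele)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataError(f"position must be ≥ 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele.upper()) <= _ALLELE_CHARS:
                raise DataError(f"invalid allele {allele!r}")


@dataclass
class SnpExclusionList:
    """Known-SNP lookup by exact (chrom, pos, ref, alt) key or rsID."""

    keys: set[tuple[str, int, str, str]] = field(default_factory=set)
    rsids: set[str] = field(default_factory=set)

    @classmethod
    def from_file(cls, path: str | Path) -> "SnpExclusionList":
        """Load a SNP list: one rsID per line, or 4-column chrom/pos/ref/alt."""
        keys, rsids = set(), set()
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    rsids.add(parts[0])
                elif len(parts) >= 4:
                    try:
                        keys.add((parts[0], int(parts[1]), parts[2], parts[3]))
                    except ValueError as exc:
                        raise ParseError(
                            f"bad SNP list row at line {lineno}: {line!r}"
                        ) from exc
                else:
                    raise ParseError(
                        f"bad SNP list row at line {lineno}: {line!r}"
                    )
        return cls(keys=keys, rsids=rsids)

    def __contains__(self, record: VariantRecord) -> bool:
        if record.rsid and record.rsid in self.rsids:
            return True
        return (record.chrom, record.pos, record.ref, record.alt) in self.keys


class GeneIntervalMap:
    """Point-in-interval gene lookup over 1-based inclusive gene spans."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, str]]):
        """``intervals``: (chrom, start, end, gene), 1-based inclusive."""
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end, gene in intervals:
            if end < start:
                raise DataError(f"interval end < start for gene {gene!r}")
            # IntervalTree is half-open; +1 keeps the end position inside
            self._trees.setdefault(chrom, IntervalTree()).addi(
                start, end + 1, gene
            )

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneIntervalMap":
        """Build from BED (0-based half-open; name column = gene symbol)."""
        intervals = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"BED row needs ≥4 columns at line {lineno}")
                try:
                    start0, end0 = int(parts[1]), int(parts[2])
                except ValueError as exc:
                    raise ParseError(f"bad BED coordinates at line {lineno}") from exc
                intervals.append((parts[0], start0 + 1, end0, parts[3]))
        return cls(intervals)

    def genes_at(self, chrom: str, pos: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.at(pos)}

    @property
    def genes(self) -> list[str]:
        return sorted({iv.data for tree in self._trees.values() for iv in tree})


@dataclass
class IndicatorResult:
    """Gene-level binary vector plus an account of unmapped records."""

    indicators: pd.Series  # gene -> 0/1
    n_records: int
    unmapped: list[VariantRecord] = field(default_factory=list)
    n_filtered: int = 0  # records removed by the SNP exclusion list


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_variants(path: str | Path, require_pass: bool = True) -> list[VariantRecord]:
    """Read VCF 4.x or ANNOVAR-style tabular variants into normalized records.

    Multi-allelic VCF rows are split into one record per alternate allele.
    With ``require_pass`` (default) only FILTER = PASS/'.' VCF rows are kept.
    """
    path = Path(path)
    if _looks_like_vcf(path):
        return _read_vcf(path, require_pass=require_pass)
    return _read_annovar(path)


def _looks_like_vcf(path: Path) -> bool:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF") or path.suffix == ".vcf"


def _read_vcf(path: Path, require_pass: bool) -> list[VariantRecord]:
    records = []
    for v in VCF(str(path)):
        # cyvcf2 reports FILTER=None for both PASS and '.'
        if require_pass and v.FILTER is not None:
            continue
        rsid = v.ID if v.ID not in (None, ".") else None
        gene = None
        info_gene = v.INFO.get("GENE")
        if info_gene:
            gene = str(info_gene)
        for alt in v.ALT:
            records.append(VariantRecord(
                chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt,
                gene=gene, rsid=rsid,
            ))
    return records


def _read_annovar(path: Path) -> list[VariantRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ParseError(
                    f"ANNOVAR-style row needs ≥5 columns at line {lineno}"
                )
            chrom, start, _end, ref, alt = parts[:5]
            gene = parts[5] if len(parts) > 5 and parts[5] else None
            try:
                pos = int(start)
            except ValueError as exc:
                raise ParseError(
                    f"bad position {start!r} at line {lineno}"
                ) from exc
            try:
                records.append(VariantRecord(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                ))
            except DataError as exc:
                raise ParseError(f"malformed row at line {lineno}: {exc}") from exc
    return records


def write_variants_annovar(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records in the 6-column ANNOVAR-style dialect (round-trippable)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            end = r.pos + max(len(r.ref), 1) - 1
            fh.write(f"{r.chrom}\t{r.pos}\t{end}\t{r.ref}\t{r.alt}\t{r.gene or ''}\n")


# ---------------------------------------------------------------------------
# Indicators
# ---------------------------------------------------------------------------

def variants_to_indicators(
    records: Sequence[VariantRecord],
    gene_map: GeneIntervalMap | None,
    snp_list: SnpExclusionList | None,
    mode: str,
    genes: Sequence[str] | None = None,
) -> IndicatorResult:
    """Collapse variant records into a binary gene vector.

    A gene is 1 iff ≥1 qualifying variant annotates to it (via the record's
    own gene column, else the interval map). ``mode="mutation"`` first drops
    variants in the SNP exclusion list; ``mode="variation"`` uses all. The
    gene universe is ``genes`` if given, else the map's genes plus any
    annotated genes seen. Records mapping to no gene are returned in
    ``unmapped``.
    """
    if mode not in ("mutation", "variation"):
        raise ValueError("mode must be 'mutation' or 'variation'")
    hit_genes: set[str] = set()
    unmapped: list[VariantRecord] = []
    n_filtered = 0
    for r in records:
        if mode == "mutation" and snp_list is not None and r in snp_list:
            n_filtered += 1
            continue
        targets: set[str] = set()
        if r.gene:
            targets.add(r.gene)
        elif gene_map is not None:
            targets = gene_map.genes_at(r.chrom, r.pos)
        if targets:
            hit_genes |= targets
        else:
            unmapped.append(r)
    if genes is None:
        universe = sorted(
            set(gene_map.genes if gene_map is not None else []) | hit_genes
        )
    else:
        universe = list(genes)
    vec = pd.Series(
        [1 if g in hit_genes else 0 for g in universe],
        index=universe, dtype=int, name=mode,
    )
    return IndicatorResult(
        indicators=vec, n_records=len(records),
        unmapped=unmapped, n_filtered=n_filtered,
    )
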