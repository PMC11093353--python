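"""Assign binding regions to genes, classify genomic context, scan for HREs,
and cross-reference with expression-derived regulation lists.

Distance convention: intervals are held 0-based half-open internally, but
distances between disjoint intervals are the difference of the nearest
boundary *coordinates* on the 1-based inclusive scale (the convention that
reproduces published promoter distances such as "1453 bp upstream").  For
half-open intervals a=[s1,e1), b=[s2,e2) with a entirely left of b this is
``s2 + 1 - e1``.

Assignment: candidate genes lie within 6 kb of the region; if any candidate
is differentially expressed (under hypoxia or in a HIF-1-stabilizing
mutant), all such candidates are assigned (basis ``de_priority``), otherwise
the single nearest candidate is (basis ``nearest``, ties to the smaller
start coordinate).

HRE: the hypoxia response element RCGTG (R = A or G); its mandatory core is
CGTG.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError

__all__ = [
    "GeneModel",
    "PeakAnnotation",
    "Assignment",
    "gene_distance",
    "assign_region",
    "classify_context",
    "scan_hre",
    "cross_reference",
]

MAX_ASSIGN_DISTANCE = 6000

CONTEXT_CATEGORIES = (
    "upstream",
    "upstream_5utr_overlap",
    "intron",
    "coding",
    "three_prime_utr",
    "downstream",
)


@dataclass
class GeneModel:
    """A gene's genomic structure (all intervals 0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise DataError("gene span must be non-empty")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise DataError(f"exon ({s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        """Transcription start: 0-based position of the first transcribed base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(ex, ex[1:])
            if a_end < b_start
        ]


@dataclass
class Assignment:
    gene_id: str
    distance: int
    basis: str  # "de_priority" | "nearest"
    context: str | None = None


@dataclass
class PeakAnnotation:
    region_id: str
    chrom: str
    start: int
    end: int
    assignments: list[Assignment] = field(default_factory=list)
    hre_hits: list[tuple[int, str]] = field(default_factory=list)

    @property
    def assigned_genes(self) -> list[str]:
        return [a.gene_id for a in self.assignments]


def _overlap_len(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def gene_distance(
    region: tuple[int, int], gene_span: tuple[int, int]
) -> int:
    """Distance in bp between two intervals on one chromosome.

    0 when they overlap; otherwise the absolute difference of the nearest
    boundary coordinates on the 1-based inclusive scale.  Symmetric.
    """
    (s1, e1), (s2, e2) = region, gene_span
    if _overlap_len(region, gene_span) > 0:
        return 0
    if e1 <= s2:  # region left of gene
        return s2 + 1 - e1
    return s1 + 1 - e2


def assign_region(
    region,
    annotation: Mapping[str, Sequence[GeneModel]] | Sequence[GeneModel],
    de_genes: set[str] | frozenset[str] = frozenset(),
    max_distance: int = MAX_ASSIGN_DISTANCE,
    region_id: str | None = None,
) -> PeakAnnotation:
    """Assign one binding region to target gene(s) within ``max_distance``.

    ``region`` needs attributes ``chrom``, ``start``, ``end`` (a
    :class:`~hifseek.chip.BindingRegion` works).  ``annotation`` is either a
    chromosome->genes mapping or a flat gene list.  DE candidates take
    priority over proximity; with none, the nearest gene wins (tie: smaller
    start).  Each assignment carries its genomic-context category.
    """
    if isinstance(annotation, Mapping):
        genes = list(annotation.get(region.chrom, ()))
    else:
        genes = [g for g in annotation if g.chrom == region.chrom]
    interval = (region.start, region.end)
    candidates = [
        (g, gene_distance(interval, g.span))
        for g in genes
    ]
    candidates = [(g, d) for g, d in candidates if d <= max_distance]

    ann = PeakAnnotation(
        region_id=region_id or f"{region.chrom}:{region.start}-{region.end}",
        chrom=region.chrom,
        start=region.start,
        end=region.end,
    )
    if not candidates:
        return ann
    de_hits = [(g, d) for g, d in candidates if g.gene_id in de_genes]
    if de_hits:
        chosen = [(g, d, "de_priority") for g, d in de_hits]
    else:
        g, d = min(candidates, key=lambda gd: (gd[1], gd[0].start))
        chosen = [(g, d, "nearest")]
    for g, d, basis in chosen:
        ann.assignments.append(
            Assignment(
                gene_id=g.gene_id,
                distance=d,
                basis=basis,
                context=classify_context(interval, g),
            )
        )
    return ann


def classify_context(region: tuple[int, int], gene: GeneModel) -> str:
    """Classify a region's position relative to one gene model.

    Disjoint regions are upstream/downstream by strand-aware position; a
    region overlapping the 5' UTR while extending beyond the upstream edge of
    the gene span is ``upstream_5utr_overlap``; otherwise the feature class
    (intron, coding, 3' UTR) with maximal overlap wins, ties broken
    intron > coding > three_prime_utr.
    """
    s, e = region
    if e <= s:
        raise DataError("empty region interval")
    if _overlap_len(region, gene.span) == 0:
        before = e <= gene.start  # region left of the gene on the chromosome
        if gene.strand == "+":
            return "upstream" if before else "downstream"
        return "downstream" if before else "upstream"

    utr5_ov = sum(_overlap_len(region, u) for u in gene.five_utr)
    extends_upstream = s < gene.start if gene.strand == "+" else e > gene.end
    if utr5_ov > 0 and extends_upstream:
        return "upstream_5utr_overlap"

    overlaps = {
        "intron": sum(_overlap_len(region, iv) for iv in gene.introns()),
        "coding": sum(_overlap_len(region, iv) for iv in gene.cds),
        "three_prime_utr": sum(_overlap_len(region, iv) for iv in gene.three_utr),
    }
    if max(overlaps.values()) == 0:
        # interior overlap confined to the 5' UTR
        if utr5_ov > 0:
            return "upstream_5utr_overlap"
        # span overlap outside any annotated feature: treat as intronic space
        return "intron"
    priority = {"intron": 0, "coding": 1, "three_prime_utr": 2}
    return max(overlaps, key=lambda k: (overlaps[k], -priority[k]))


_MOTIFS = {"full": ("ACGTG", "GCGTG"), "core": ("CGTG",)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def scan_hre(
    sequence: str, mode: str = "core", strands: str = "given"
) -> list[tuple[int, str]]:
    """Find hypoxia-response-element matches in a sequence.

    ``mode='full'`` matches RCGTG (ACGTG or GCGTG), ``mode='core'`` the
    mandatory core CGTG.  ``strands='both'`` additionally scans the reverse
    complement, reporting minus-strand hits at the offset of the match on the
    forward sequence.  Overlapping matches are all reported, sorted by
    offset.  Returns (offset, strand) pairs.
    """
    if mode not in _MOTIFS:
        raise DataError(f"mode must be one of {sorted(_MOTIFS)}")
    if strands not in ("given", "both"):
        raise DataError("strands must be 'given' or 'both'")
    seq = sequence.upper()
    if seq and not set(seq) <= set("ACGTN"):
        raise DataError("sequence must be over the A/C/G/T/N alphabet")
    motifs = _MOTIFS[mode]
    pattern = re.compile("(?=(" + "|".join(motifs) + "))")
    hits = [(m.start(), "+") for m in pattern.finditer(seq)]
    if strands == "both":
        k = len(motifs[0])
        rc = _revcomp(seq)
        hits += [
            (len(seq) - m.start() - k, "-") for m in pattern.finditer(rc)
        ]
    return sorted(hits)


TABLE_ROWS = (
    "hif1_positive",
    "hif1_negative",
    "mutant_up",
    "mutant_down",
    "unlabeled",
)


def cross_reference(
    annotations: Iterable[PeakAnnotation],
    labels: pd.DataFrame,
) -> dict[str, list[str]]:
    """Partition region-assigned genes by their expression regulation labels.

    ``labels`` is the gene-indexed boolean table from
    :func:`hifseek.expression.classify`.  Rows: positively / negatively
    HIF-1-regulated under hypoxia, up- / down-regulated in at least one
    HIF-1-stabilizing mutant, and unlabeled.  A gene may appear in several
    rows.
    """
    assigned = sorted(
        {a.gene_id for ann in annotations for a in ann.assignments}
    )
    mut_up_cols = [c for c in labels.columns if c.startswith("mutant_up:")]
    mut_dn_cols = [c for c in labels.columns if c.startswith("mutant_down:")]
    out: dict[str, list[str]] = {row: [] for row in TABLE_ROWS}
    for g in assigned:
        any_row = False
        if g in labels.index:
            row = labels.loc[g]
            if bool(row.get("hif1_positive", False)):
                out["hif1_positive"].append(g)
                any_row = True
            if bool(row.get("hif1_negative", False)):
                out["hif1_negative"].append(g)
                any_row = True
            if any(bool(row[c]) for c in mut_up_cols):
                out["mutant_up"].append(g)
                any_row = True
            if any(bool(row[c]) for c in mut_dn_cols):
                out["mutant_down"].append(g)
                any_row = True
        if not any_row:
            out["unlabeled"].append(g)
    return out
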