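"""Genome-wide-significant locus detection and gene-to-locus mapping.

A locus is seeded by any variant with p < 1e-7 (strict) in any study of the
panel, expanded by a 500 kb flank on each side, and overlapping or book-ended
intervals on the same chromosome are merged (distance-0 merge, the default
behaviour of the standard BED interval-merging tool).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError
from .sumstats import AssocTable, VariantKey, chrom_sort_key

GENOME_WIDE_P = 1e-7
DEFAULT_FLANK = 500_000


@dataclass(frozen=True)
class Locus:
    """A merged genome-wide-significant interval, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    source_variants: tuple[VariantKey, ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        for v in self.source_variants:
            if not (str(v.chrom) == str(self.chrom) and self.start <= v.pos <= self.end):
                raise ValueError(f"source variant {v} outside locus {self.label}")

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start}–{self.end}"

    @classmethod
    def from_label(cls, label: str) -> "Locus":
        chrom, _, rest = label.partition(":")
        start, _, end = rest.replace("-", "–").partition("–")
        return cls(chrom, int(start), int(end))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return str(chrom) == str(self.chrom) and start <= self.end and end >= self.start

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.start, self.end)


def merge_intervals(intervals: Iterable[tuple[str, int, int]]) -> list[Locus]:
    """Merge overlapping or book-ended 1-based inclusive intervals per chromosome.

    Book-ended means end_i + 1 == start_j: the union of covered bases is
    contiguous, matching distance-0 merging. Idempotent; output sorted by
    canonical chromosome order then start.
    """
    rows = sorted(
        ((str(c), int(s), int(e)) for c, s, e in intervals),
        key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]),
    )
    for c, s, e in rows:
        if s > e:
            raise InputError(f"invalid interval {c}:{s}-{e}")
    merged: list[list] = []
    for c, s, e in rows:
        if merged and merged[-1][0] == c and s <= merged[-1][2] + 1:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([c, s, e])
    return [Locus(c, s, e) for c, s, e in merged]


def find_loci(tables: Sequence[AssocTable], p_threshold: float = GENOME_WIDE_P,
              flank: int = DEFAULT_FLANK) -> list[Locus]:
    """Identify genome-wide-significant loci across a panel of studies.

    Every variant with p < ``p_threshold`` (strict) in ANY table contributes
    an interval [pos - flank, pos + flank] floored at 1; intervals are then
    merged per chromosome. Source variants are attached to the merged loci.
    Returns an empty list when nothing is significant.
    """
    if not (0 < p_threshold < 1):
        raise InputError(f"p_threshold must be in (0,1), got {p_threshold}")
    if flank < 0:
        raise InputError(f"flank must be >= 0, got {flank}")
    seeds: list[VariantKey] = []
    for t in tables:
        hit = t.df[t.df["p"] < p_threshold]
        seeds.extend(
            VariantKey(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
            for r in hit.itertuples()
        )
    if not seeds:
        return []
    seeds = sorted(set(seeds))
    merged = merge_intervals(
        (v.chrom, max(1, v.pos - flank), v.pos + flank) for v in seeds)
    out = []
    for loc in merged:
        sv = tuple(v for v in seeds
                   if str(v.chrom) == loc.chrom and loc.start <= v.pos <= loc.end)
        out.append(Locus(loc.chrom, loc.start, loc.end, source_variants=sv))
    return out


def map_genes_to_loci(genes: pd.DataFrame, loci: Sequence[Locus]
                      ) -> dict[str, list[str]]:
    """Assign genes to loci by >= 1 bp overlap of the gene body interval.

    ``genes`` carries columns gene_id, gene_name, chrom, start, end (1-based
    inclusive). Returns ``{locus.label: [gene_id, ...]}``; a gene may appear
    under several loci.
    """
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in genes.columns:
            raise InputError(f"gene annotation missing column {col!r}")
    mapping: dict[str, list[str]] = {loc.label: [] for loc in loci}
    for r in genes.itertuples():
        for loc in loci:
            if loc.overlaps(str(r.chrom), int(r.start), int(r.end)):
                mapping[loc.label].append(str(r.gene_id))
    return mapping


def loci_to_bed(loci: Sequence[Locus]) -> pd.DataFrame:
    """Loci as a 6-column BED frame (0-based half-open)."""
    return pd.DataFrame({
        "chrom": [l.chrom for l in loci],
        "start": [l.start - 1 for l in loci],
        "end": [l.end for l in loci],
        "name": [l.label for l in loci],
        "score": 0,
        "strand": ".",
    })


def locus_summary_table(loci: Sequence[Locus], tables: Sequence[AssocTable]
                        ) -> pd.DataFrame:
    """Per-locus minimum p-value per study (S1-style report)."""
    rows = []
    for loc in loci:
        row = {"locus": loc.label}
        for t in tables:
            sub = t.restrict(loc.chrom, loc.start, loc.end)
            sid = getattr(t.meta, "study_id", str(t.meta))
            row[f"min_p_{sid}"] = sub.min_p() if len(sub) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
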