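"""Interval arithmetic over ChIP-seq peak sets.

A *cistrome* is the genome-wide set of binding sites of a transcription
factor under one condition. Comparing cistromes between conditions starts
from three operations implemented here:

* :func:`partition_peak_sets` — Venn-partition two peak sets into common
  and condition-unique peaks (peak-centric, per input set);
* :func:`annotate_genomic_distribution` — classify each peak by the genomic
  feature its midpoint falls in (promoter > exon > intron > distal);
* :func:`select_top_peaks` — keep the n highest-scoring peaks, where the
  score is the peak caller's ``-10 * log10(q-value)``.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "VennPartition",
    "GenomeAnnotation",
    "partition_peak_sets",
    "annotate_genomic_distribution",
    "select_top_peaks",
]

_VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """One genomic interval, 0-based half-open, with a peak score."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"strand must be one of {_VALID_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


class PeakSet:
    """A labelled, coordinate-sorted collection of peaks with unique names."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            dupes = {n for n in names if names.count(n) > 1}
            raise ValueError(f"duplicate peak names in set {label!r}: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.label == other.label and self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"

    def subset(self, names: set[str], label: str | None = None) -> "PeakSet":
        return PeakSet(label or self.label, [iv for iv in self.intervals if iv.name in names])

    # -- BED6 round trip ---------------------------------------------------

    @classmethod
    def from_bed(cls, path: str | Path, label: str | None = None) -> "PeakSet":
        """Read BED6 (tab-separated, no header); tolerate BED3 by filling defaults."""
        path = Path(path)
        intervals = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{i + 1}: fewer than 3 BED columns")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else f"peak_{i + 1}"
                score = float(parts[4]) if len(parts) > 4 else 0.0
                strand = parts[5] if len(parts) > 5 else "."
                intervals.append(GenomicInterval(chrom, start, end, name, score, strand))
        return cls(label or path.stem, intervals)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
                )


@dataclass
class VennPartition:
    """Peak-centric Venn partition of two peak sets.

    Counts are reported per input set: a peak of A is *common* iff it
    overlaps at least one peak of B (and vice versa), so ``common_a`` and
    ``common_b`` may differ in size when overlaps are many-to-many.
    """

    labels: tuple[str, str]
    common_a: PeakSet
    common_b: PeakSet
    unique_a: PeakSet
    unique_b: PeakSet

    @property
    def counts(self) -> dict[str, int]:
        return {
            "common_a": len(self.common_a),
            "common_b": len(self.common_b),
            "unique_a": len(self.unique_a),
            "unique_b": len(self.unique_b),
        }

    def write(self, outdir: str | Path) -> None:
        """Write the four member BED files plus a JSON count summary."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        a, b = self.labels
        self.common_a.to_bed(outdir / f"common_{a}.bed")
        self.common_b.to_bed(outdir / f"common_{b}.bed")
        self.unique_a.to_bed(outdir / f"unique_{a}.bed")
        self.unique_b.to_bed(outdir / f"unique_{b}.bed")
        with open(outdir / "venn_counts.json", "w") as fh:
            json.dump({"labels": list(self.labels), **self.counts}, fh, indent=2)
            fh.write("\n")


@dataclass
class GenomeAnnotation:
    """Gene annotation: per gene (gene_id, chrom, strand, tss) plus optional
    feature intervals (exons/introns) used for genomic-distribution calls."""

    genes: pd.DataFrame  # columns: gene_id, chrom, strand, tss
    features: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss"}
        missing = required - set(self.genes.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def _overlaps(a: GenomicInterval, b: GenomicInterval, max_gap: int) -> bool:
    return a.chrom == b.chrom and a.start < b.end + max_gap and b.start < a.end + max_gap


def _build_tree(peaks: Iterable[GenomicInterval], pad: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in peaks:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start - pad, iv.end + pad, iv.name)
    return trees


def partition_peak_sets(a: PeakSet, b: PeakSet, max_gap: int = 0) -> VennPartition:
    """Venn-partition two peak sets.

    A peak is *common* iff it overlaps (by >= 1 bp, after extending ends by
    ``max_gap``) at least one peak of the other set; otherwise it is unique
    to its own set. Chromosomes present in only one set are allowed — their
    peaks are unique by definition.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    trees_b = _build_tree(b, max_gap)
    trees_a = _build_tree(a, 0)

    def split(peaks: PeakSet, trees: dict[str, IntervalTree]) -> tuple[list, list]:
        common, unique = [], []
        for iv in peaks:
            tree = trees.get(iv.chrom)
            if tree is not None and tree.overlap(iv.start, iv.end):
                common.append(iv)
            else:
                unique.append(iv)
        return common, unique

    common_a, unique_a = split(a, trees_b)
    # pad applied once (to B's tree when querying A, to A's tree when querying
    # B) so the criterion "gap <= max_gap" is identical in both directions
    trees_a_pad = _build_tree(a, max_gap)
    common_b, unique_b = split(b, trees_a_pad)
    del trees_a
    return VennPartition(
        labels=(a.label, b.label),
        common_a=PeakSet(f"common_{a.label}", common_a),
        common_b=PeakSet(f"common_{b.label}", common_b),
        unique_a=PeakSet(f"unique_{a.label}", unique_a),
        unique_b=PeakSet(f"unique_{b.label}", unique_b),
    )


_CATEGORIES = ("promoter", "exon", "intron", "distal_intergenic")


def annotate_genomic_distribution(
    peaks: PeakSet,
    ann: GenomeAnnotation,
    promoter_window: int = 3000,
) -> pd.DataFrame:
    """Classify each peak into exactly one genomic category by its midpoint.

    Precedence: promoter (midpoint within ``promoter_window`` of a TSS) >
    exon > intron > distal-intergenic. Exon/intron calls require feature
    intervals on the annotation; without them, non-promoter peaks are
    distal. Returns a tidy frame with one row per category (count, fraction).
    """
    if len(peaks) == 0:
        return pd.DataFrame({"category": list(_CATEGORIES), "count": 0, "fraction": 0.0})

    tss_by_chrom: dict[str, list[int]] = {}
    for _, row in ann.genes.iterrows():
        tss_by_chrom.setdefault(row["chrom"], []).append(int(row["tss"]))

    feature_trees = {kind: _build_tree(ivs, 0) for kind, ivs in ann.features.items()}

    def classify(iv: GenomicInterval) -> str:
        mid = iv.midpoint
        for tss in tss_by_chrom.get(iv.chrom, ()):
            if abs(mid - tss) <= promoter_window:
                return "promoter"
        for kind in ("exon", "intron"):
            tree = feature_trees.get(kind, {}).get(iv.chrom)
            if tree is not None and tree.overlap(mid, mid + 1):
                return kind
        return "distal_intergenic"

    counts = {cat: 0 for cat in _CATEGORIES}
    for iv in peaks:
        counts[classify(iv)] += 1
    n = len(peaks)
    return pd.DataFrame(
        {
            "category": list(_CATEGORIES),
            "count": [counts[c] for c in _CATEGORIES],
            "fraction": [counts[c] / n for c in _CATEGORIES],
        }
    )


def select_top_peaks(peaks: PeakSet, n: int) -> PeakSet:
    """The ``n`` highest-score peaks; ties broken by (chrom, start, end) so
    the selection is deterministic. ``n >= len(peaks)`` returns all peaks."""
    if n < 0:
        raise ValueError("n must be >= 0")
    ranked = sorted(peaks, key=lambda iv: (-iv.score, iv.sort_key()))
    return PeakSet(f"{peaks.label}_top{n}", ranked[:n])
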