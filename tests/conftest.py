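import numpy as np
import pandas as pd
import pytest

from arsig.cistrome import GenomeAnnotation, GenomicInterval, PeakSet
from arsig.simulate import (
    SimConfig,
    generate_condition_peaks,
    generate_counts,
    generate_genome_annotation,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A scaled-down study for fast unit tests (same planted structure)."""
    return SimConfig(
        seed=42,
        n_genes=300,
        n_chroms=2,
        chrom_length=4_000_000,
        n_peaks_common=60,
        n_peaks_unique_A=40,
        n_peaks_unique_B=30,
        n_motifs=50,
        n_shifted_motifs=4,
        n_decoy_regulators=8,
        n_cohort_samples=80,
        n_background_genes=100,
    )


@pytest.fixture
def small_world(small_cfg):
    """annotation + peaks + truth + counts + design for the small study."""
    ann = generate_genome_annotation(small_cfg)
    peaks_a, peaks_b, truth = generate_condition_peaks(small_cfg, ann)
    counts, design = generate_counts(small_cfg, ann, truth)
    return {
        "cfg": small_cfg, "ann": ann, "peaks_a": peaks_a, "peaks_b": peaks_b,
        "truth": truth, "counts": counts, "design": design,
    }


def random_peakset(rng, label, n, chroms=("chr1", "chr2"), span=100_000, max_len=800):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(
            GenomicInterval(
                chroms[int(rng.integers(len(chroms)))], start, start + length,
                f"{label}_{i}", round(float(rng.random() * 100), 3), ".",
            )
        )
    return PeakSet(label, ivs)


def brute_force_partition(a, b, max_gap=0):
    """O(n^2) pairwise-overlap oracle for the peak-centric Venn partition."""

    def overlaps(x, y):
        return (x.chrom == y.chrom and x.start < y.end + max_gap
                and y.start < x.end + max_gap)

    common_a = {x.name for x in a if any(overlaps(x, y) for y in b)}
    common_b = {y.name for y in b if any(overlaps(y, x) for x in a)}
    return common_a, common_b


def toy_annotation(tss_list, chrom="chr1"):
    return GenomeAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(tss_list))],
                "chrom": chrom,
                "strand": "+",
                "tss": tss_list,
            }
        )
    )


def make_de_table(rows):
    """rows: dict gene -> (log2fc, p, fdr)."""
    df = pd.DataFrame(
        [
            {"gene_id": g, "log2fc": v[0], "mean_expr": 100.0, "p": v[1], "fdr": v[2]}
            for g, v in rows.items()
        ]
    ).set_index("gene_id")
    df["direction"] = "ns"
    return df


def make_target_table(genes, targets):
    return pd.DataFrame(
        {
            "is_direct_target": [g in targets for g in genes],
            "supporting_peaks": ["p1" if g in targets else "" for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
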