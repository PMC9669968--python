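"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the structure of a two-condition cistrome/
transcriptome study: two peak sets sharing a planted common fraction plus
condition-unique fractions placed near the TSSs of planted gene classes;
negative-binomial count matrices in which the planted A-unique, B-unique
and common gene classes are shifted by a known log2 fold-change in the
matching condition groups; motif z-score tables with a planted rank
shift; a regulator -> target network containing one planted regulator
enriched for the B-unique class among decoys; a partially overlapping
"externally regulated" gene set; and an expression + survival cohort
whose hazard depends on a planted signature score.

Everything is deterministic under ``SimConfig.seed`` (each generator
derives an independent stream from the seed, so generators may be called
in any order), and every emitted file round-trips through the package's
own readers. Read counts, peak shapes, sequence content and batch
effects are deliberately not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cistrome import GenomeAnnotation, GenomicInterval, PeakSet

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "generate_genome_annotation",
    "generate_condition_peaks",
    "generate_counts",
    "generate_motif_tables",
    "generate_regulator_network",
    "generate_gene_sets",
    "generate_cohort",
    "simulate_all",
]

# independent, order-insensitive substreams per generator
_STREAMS = {
    "annotation": 1, "peaks": 2, "counts": 3, "motifs": 4,
    "network": 5, "gene_sets": 6, "cohort": 7,
}


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults describe the benchmark conditions every recovery and
    calibration test runs under: 2,000 genes, 60 planted DE genes per
    class (3% each of A-unique, B-unique, common), a planted log2
    fold-change of 2, NB dispersion 0.05 and 5 samples per group.
    """

    seed: int = 0
    n_genes: int = 2000
    n_chroms: int = 5
    chrom_length: int = 20_000_000
    n_samples_per_group: int = 5
    n_peaks_common: int = 300
    n_peaks_unique_A: int = 300
    n_peaks_unique_B: int = 300
    frac_peaks_near_tss: float = 0.6
    tss_window: int = 10_000
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    frac_de_A_unique: float = 0.03
    frac_de_B_unique: float = 0.03
    frac_de_common: float = 0.03
    frac_de_up: float = 0.8  # fraction of planted DE genes shifted upward
    ezh2_overlap_frac: float = 0.5
    hazard_beta: float = 1.0
    censor_rate: float = 0.3
    # secondary knobs
    include_double_group: bool = True
    nb_dispersion_jitter: float = 0.0  # sd of per-gene log-dispersion jitter
    n_motifs: int = 200
    n_shifted_motifs: int = 10
    motif_shift: float = 5.0
    n_decoy_regulators: int = 30
    regulator_coverage: float = 0.8
    n_cohort_samples: int = 200
    n_background_genes: int = 500
    baseline_median_survival: float = 24.0  # months

    def __post_init__(self) -> None:
        fracs = {
            "frac_peaks_near_tss": self.frac_peaks_near_tss,
            "frac_de_A_unique": self.frac_de_A_unique,
            "frac_de_B_unique": self.frac_de_B_unique,
            "frac_de_common": self.frac_de_common,
            "ezh2_overlap_frac": self.ezh2_overlap_frac,
            "frac_de_up": self.frac_de_up,
            "censor_rate": self.censor_rate,
            "regulator_coverage": self.regulator_coverage,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if (self.frac_de_A_unique + self.frac_de_B_unique + self.frac_de_common) > 1:
            raise ValueError("planted DE fractions must sum to <= 1")
        for name in ("n_genes", "n_chroms", "chrom_length", "n_samples_per_group",
                     "n_peaks_common", "n_peaks_unique_A", "n_peaks_unique_B",
                     "tss_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for recovery tests."""

    planted_unique_genes_A: set[str] = field(default_factory=set)
    planted_unique_genes_B: set[str] = field(default_factory=set)
    planted_common_genes: set[str] = field(default_factory=set)
    planted_direct_targets: set[str] = field(default_factory=set)
    planted_ezh2_regulated: set[str] = field(default_factory=set)
    planted_up_genes: set[str] = field(default_factory=set)
    planted_down_genes: set[str] = field(default_factory=set)
    peak_labels: dict[str, str] = field(default_factory=dict)  # peak id -> class

    def __post_init__(self) -> None:
        a, b, c = (self.planted_unique_genes_A, self.planted_unique_genes_B,
                   self.planted_common_genes)
        if a & b or a & c or b & c:
            raise ValueError("planted gene classes must be pairwise disjoint")

    def to_json(self, path: str | Path) -> None:
        d = {
            k: sorted(v) if isinstance(v, set) else v
            for k, v in asdict(self).items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        for k in ("planted_unique_genes_A", "planted_unique_genes_B",
                  "planted_common_genes", "planted_direct_targets",
                  "planted_ezh2_regulated", "planted_up_genes",
                  "planted_down_genes"):
            d[k] = set(d[k])
        return cls(**d)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_genome_annotation(cfg: SimConfig) -> GenomeAnnotation:
    """Place ``n_genes`` genes uniformly (collision-free TSSs) across
    ``n_chroms`` chromosomes with random strands."""
    rng = cfg.rng("annotation")
    if cfg.n_genes == 0:
        empty = pd.DataFrame(columns=["gene_id", "chrom", "strand", "tss"])
        return GenomeAnnotation(empty)
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    if max(per_chrom) > cfg.chrom_length:
        raise ValueError(
            f"chrom_length={cfg.chrom_length} cannot host {max(per_chrom)} "
            "collision-free TSSs; increase chrom_length or n_chroms"
        )
    rows = []
    gid = iter(_gene_ids(cfg.n_genes))
    for c, n_c in enumerate(per_chrom, start=1):
        tss = _draw_unique(rng, cfg.chrom_length, n_c)
        strands = rng.choice(["+", "-"], size=n_c)
        for t, s in zip(np.sort(tss), strands):
            rows.append({"gene_id": next(gid), "chrom": f"chr{c}",
                         "strand": str(s), "tss": int(t)})
    return GenomeAnnotation(pd.DataFrame(rows))


def _draw_unique(rng: np.random.Generator, high: int, size: int) -> np.ndarray:
    """Distinct integers uniform on [0, high) without materializing the range."""
    out: set[int] = set()
    while len(out) < size:
        out.update(int(x) for x in rng.integers(0, high, size=size - len(out)))
    return np.array(sorted(out))


def generate_condition_peaks(
    cfg: SimConfig, ann: GenomeAnnotation
) -> tuple[PeakSet, PeakSet, SyntheticTruth]:
    """Two condition peak sets with planted common/unique structure.

    Planted gene classes (A-unique, B-unique, common DE) are drawn
    disjointly; ``frac_peaks_near_tss`` of each peak class is placed with
    its midpoint within ``tss_window`` of a planted gene of the matching
    class (every planted gene is covered first, so each becomes a direct
    target), and the remainder is placed with midpoints >= 2*tss_window
    from every TSS. Common peaks have identical coordinates and names in
    both sets; scores are positive.
    """
    if len(ann) == 0:
        raise ValueError("annotation is empty; generate genes first")
    rng = cfg.rng("peaks")
    genes = ann.genes
    all_ids = list(genes["gene_id"])
    n_a = round(cfg.frac_de_A_unique * cfg.n_genes)
    n_b = round(cfg.frac_de_B_unique * cfg.n_genes)
    n_c = round(cfg.frac_de_common * cfg.n_genes)
    chosen = rng.choice(len(all_ids), size=n_a + n_b + n_c, replace=False)
    planted_a = {all_ids[i] for i in chosen[:n_a]}
    planted_b = {all_ids[i] for i in chosen[n_a:n_a + n_b]}
    planted_c = {all_ids[i] for i in chosen[n_a + n_b:]}

    tss_of = dict(zip(genes["gene_id"], genes["tss"].astype(int)))
    chrom_of = dict(zip(genes["gene_id"], genes["chrom"]))
    tss_by_chrom = {
        c: np.sort(sub["tss"].to_numpy()) for c, sub in genes.groupby("chrom")
    }
    chrom_names = sorted(tss_by_chrom)

    # registry of placed peaks so peaks of *different* classes never overlap:
    # that keeps the planted common/unique labels exactly recoverable by the
    # downstream partition (same-class overlaps are harmless)
    placed: dict[str, list[tuple[int, int, str]]] = {}

    def collides(chrom: str, start: int, end: int, klass: str) -> bool:
        return any(
            s < end and start < e and k != klass
            for s, e, k in placed.get(chrom, ())
        )

    def register(iv: GenomicInterval, klass: str) -> GenomicInterval:
        placed.setdefault(iv.chrom, []).append((iv.start, iv.end, klass))
        return iv

    def near_peak(gene: str, name: str, klass: str) -> GenomicInterval:
        tss = tss_of[gene]
        chrom = chrom_of[gene]
        for _ in range(1000):
            width = int(rng.integers(150, 401))
            max_off = cfg.tss_window - width // 2 - 1
            lo = width // 2 + 1
            if max_off <= lo:
                off = 0
            else:
                off = int(rng.integers(lo, max_off + 1))
                if tss < cfg.tss_window:
                    pass  # keep positive offset near chromosome start
                elif tss > cfg.chrom_length - cfg.tss_window:
                    off = -off
                elif rng.random() < 0.5:
                    off = -off
            mid = tss + off
            start = max(0, mid - width // 2)
            if not collides(chrom, start, start + width, klass):
                return register(
                    GenomicInterval(chrom, start, start + width, name,
                                    _score(rng), "."),
                    klass,
                )
        raise RuntimeError(
            f"could not place a TSS-proximal peak at gene {gene} without "
            "overlapping another peak class; planted classes too crowded"
        )

    def far_peak(name: str, klass: str) -> GenomicInterval:
        for _ in range(10_000):
            width = int(rng.integers(150, 401))
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            mid = int(rng.integers(width, cfg.chrom_length - width))
            tsss = tss_by_chrom[chrom]
            j = np.searchsorted(tsss, mid)
            d = min(
                abs(mid - tsss[j - 1]) if j > 0 else np.inf,
                abs(tsss[j] - mid) if j < len(tsss) else np.inf,
            )
            start = mid - width // 2
            if d >= 2 * cfg.tss_window + width and not collides(
                chrom, start, start + width, klass
            ):
                return register(
                    GenomicInterval(chrom, start, start + width, name,
                                    _score(rng), "."),
                    klass,
                )
        raise RuntimeError(
            "could not place a decoy peak >= 2*tss_window from every TSS; "
            "genome too dense for the requested configuration"
        )

    def make_class(prefix: str, n_peaks: int, gene_pool: set[str]) -> list[GenomicInterval]:
        n_near = round(cfg.frac_peaks_near_tss * n_peaks)
        pool = sorted(gene_pool)
        out = []
        klass = prefix
        for i in range(n_peaks):
            name = f"{prefix}_{i + 1:05d}"
            if i < n_near and pool:
                gene = pool[i] if i < len(pool) else pool[int(rng.integers(len(pool)))]
                out.append(near_peak(gene, name, klass))
            elif i < n_near:
                # no planted genes in this class: fall back to any gene's TSS
                out.append(near_peak(all_ids[int(rng.integers(len(all_ids)))], name, klass))
            else:
                out.append(far_peak(name, klass))
        return out

    common = make_class("common", cfg.n_peaks_common, planted_c)
    only_a = make_class("uniqueA", cfg.n_peaks_unique_A, planted_a)
    only_b = make_class("uniqueB", cfg.n_peaks_unique_B, planted_b)

    peaks_a = PeakSet("A", common + only_a)
    peaks_b = PeakSet("B", common + only_b)

    covered = _covered_genes(common + only_a + only_b, tss_by_chrom, genes, cfg.tss_window)
    planted = planted_a | planted_b | planted_c
    planted_sorted = sorted(planted)
    up_mask = rng.random(len(planted_sorted)) < cfg.frac_de_up
    planted_up = {g for g, u in zip(planted_sorted, up_mask) if u}
    truth = SyntheticTruth(
        planted_unique_genes_A=planted_a,
        planted_unique_genes_B=planted_b,
        planted_common_genes=planted_c,
        planted_direct_targets=planted & covered,
        planted_ezh2_regulated=_ezh2_set(cfg, rng, planted_b, planted, all_ids),
        planted_up_genes=planted_up,
        planted_down_genes=planted - planted_up,
        peak_labels={
            **{iv.name: "common" for iv in common},
            **{iv.name: "A-unique" for iv in only_a},
            **{iv.name: "B-unique" for iv in only_b},
        },
    )
    return peaks_a, peaks_b, truth


def _score(rng: np.random.Generator) -> float:
    # emulates the peak caller's -10*log10(q) scale: positive, right-skewed
    return float(np.round(rng.gamma(2.0, 30.0) + 13.0, 3))


def _covered_genes(
    peaks: list[GenomicInterval],
    tss_by_chrom: dict[str, np.ndarray],
    genes: pd.DataFrame,
    window: int,
) -> set[str]:
    covered = set()
    mids_by_chrom: dict[str, list[int]] = {}
    for iv in peaks:
        mids_by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
    for chrom, mids in mids_by_chrom.items():
        mids_arr = np.sort(np.array(mids))
        sub = genes[genes["chrom"] == chrom]
        for gid, tss in zip(sub["gene_id"], sub["tss"].astype(int)):
            j = np.searchsorted(mids_arr, tss)
            d = min(
                abs(tss - mids_arr[j - 1]) if j > 0 else np.inf,
                abs(mids_arr[j] - tss) if j < len(mids_arr) else np.inf,
            )
            if d <= window:
                covered.add(gid)
    return covered


def _ezh2_set(
    cfg: SimConfig,
    rng: np.random.Generator,
    planted_b: set[str],
    planted_all: set[str],
    all_ids: list[str],
) -> set[str]:
    """Externally regulated gene set overlapping ezh2_overlap_frac of the
    planted B-unique class, padded with random non-planted genes."""
    b_sorted = sorted(planted_b)
    k = round(cfg.ezh2_overlap_frac * len(b_sorted))
    overlap = {b_sorted[i] for i in rng.choice(len(b_sorted), size=k, replace=False)} if k else set()
    others = [g for g in all_ids if g not in planted_all]
    extras = {others[i] for i in rng.choice(len(others), size=min(40, len(others)), replace=False)}
    return overlap | extras


GROUPS = ("vehicle", "A", "B", "AB")


def generate_counts(
    cfg: SimConfig, ann: GenomeAnnotation, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """NB count matrix with planted condition-specific fold-changes.

    Gene baselines are log-uniform on [20, 2000]; dispersion is
    ``nb_dispersion`` (optionally jittered per gene on the log scale).
    Planted A-unique genes are shifted by ``de_log2fc`` in group A only,
    B-unique in group B only, common genes in both; the optional fourth
    "AB" group carries all three shifts. Per-sample depth factors are
    uniform on [0.7, 1.3].
    """
    rng = cfg.rng("counts")
    gene_ids = list(ann.genes["gene_id"])
    planted = (truth.planted_unique_genes_A | truth.planted_unique_genes_B
               | truth.planted_common_genes)
    if not planted <= set(gene_ids):
        raise ValueError("planted truth gene sets must be a subset of the annotation")
    n_genes = len(gene_ids)
    base = np.exp(rng.uniform(np.log(20.0), np.log(2000.0), size=n_genes))
    disp = np.full(n_genes, cfg.nb_dispersion)
    if cfg.nb_dispersion_jitter > 0:
        disp = disp * np.exp(rng.normal(0.0, cfg.nb_dispersion_jitter, size=n_genes))

    in_a = np.fromiter((g in truth.planted_unique_genes_A for g in gene_ids), bool, n_genes)
    in_b = np.fromiter((g in truth.planted_unique_genes_B for g in gene_ids), bool, n_genes)
    in_c = np.fromiter((g in truth.planted_common_genes for g in gene_ids), bool, n_genes)
    # planted genes shift up or down by de_log2fc according to their sign
    down = np.fromiter((g in truth.planted_down_genes for g in gene_ids), bool, n_genes)
    mult = np.where(down, 2.0 ** -cfg.de_log2fc, 2.0 ** cfg.de_log2fc)
    group_mult = {
        "vehicle": np.ones(n_genes),
        "A": np.where(in_a | in_c, mult, 1.0),
        "B": np.where(in_b | in_c, mult, 1.0),
        "AB": np.where(in_a | in_b | in_c, mult, 1.0),
    }
    groups = GROUPS if cfg.include_double_group else GROUPS[:3]

    cols, names, labels = [], [], []
    for g in groups:
        for s in range(1, cfg.n_samples_per_group + 1):
            depth = rng.uniform(0.7, 1.3)
            mu = base * group_mult[g] * depth
            r = 1.0 / disp
            col = rng.negative_binomial(r, r / (r + mu))
            cols.append(col)
            names.append(f"{g}_{s}")
            labels.append(g)
    counts = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=names)
    counts.index.name = "gene_id"
    assert (counts.to_numpy() >= 0).all()
    design = pd.Series(labels, index=names, name="group")
    design.index.name = "sample"
    return counts, design


def generate_motif_tables(cfg: SimConfig) -> tuple[pd.Series, pd.Series, list[str]]:
    """Shared-universe motif z-score tables; a planted subset gains
    ``motif_shift`` z in condition B only. Returns (A, B, planted names)."""
    rng = cfg.rng("motifs")
    names = [f"MOTIF_{i:04d}" for i in range(1, cfg.n_motifs + 1)]
    base = rng.normal(0.0, 2.0, size=cfg.n_motifs)
    z_a = base + rng.normal(0.0, 0.2, size=cfg.n_motifs)
    z_b = base + rng.normal(0.0, 0.2, size=cfg.n_motifs)
    shifted_idx = rng.choice(cfg.n_motifs, size=cfg.n_shifted_motifs, replace=False)
    z_b[shifted_idx] += cfg.motif_shift
    a = pd.Series(np.round(z_a, 4), index=pd.Index(names, name="motif"), name="zscore")
    b = pd.Series(np.round(z_b, 4), index=pd.Index(names, name="motif"), name="zscore")
    return a, b, sorted(names[i] for i in shifted_idx)


def generate_regulator_network(cfg: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Regulator -> target edge list: one planted regulator covering
    ``regulator_coverage`` of the planted B-unique genes (plus random
    padding) among ``n_decoy_regulators`` decoys with random targets."""
    rng = cfg.rng("network")
    universe = _gene_ids(cfg.n_genes)
    rows = []
    b_sorted = sorted(truth.planted_unique_genes_B)
    k = round(cfg.regulator_coverage * len(b_sorted))
    covered = [b_sorted[i] for i in rng.choice(len(b_sorted), size=k, replace=False)] if k else []
    others = [g for g in universe if g not in truth.planted_unique_genes_B]
    pad = [others[i] for i in rng.choice(len(others), size=min(40, len(others)), replace=False)]
    for t in sorted(set(covered + pad)):
        rows.append({"regulator": "REG_planted", "target": t})
    for d in range(1, cfg.n_decoy_regulators + 1):
        size = int(rng.integers(40, 121))
        targets = rng.choice(len(universe), size=size, replace=False)
        for i in sorted(targets):
            rows.append({"regulator": f"REG_decoy{d:02d}", "target": universe[i]})
    return pd.DataFrame(rows, columns=["regulator", "target"])


def generate_gene_sets(cfg: SimConfig, truth: SyntheticTruth) -> dict[str, set[str]]:
    """A small GMT-style collection: the three planted classes plus random
    decoy sets, for exercising GSEA/ORA stages."""
    rng = cfg.rng("gene_sets")
    universe = _gene_ids(cfg.n_genes)
    sets = {
        "PLANTED_A_UNIQUE": set(truth.planted_unique_genes_A),
        "PLANTED_B_UNIQUE": set(truth.planted_unique_genes_B),
        "PLANTED_COMMON": set(truth.planted_common_genes),
    }
    for d in range(1, 11):
        idx = rng.choice(len(universe), size=50, replace=False)
        sets[f"DECOY_{d:02d}"] = {universe[i] for i in idx}
    return sets


def generate_cohort(
    cfg: SimConfig, sig_genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression + clinical cohort whose hazard depends on a signature score.

    Signature genes load 0.7 on a shared per-sample latent factor (so the
    mean-z signature score tracks the factor); background genes are pure
    noise. Survival times are exponential with log-hazard
    ``hazard_beta * score`` around a baseline median of
    ``baseline_median_survival`` months; a ``censor_rate`` fraction of
    samples (independent of score and time) is censored uniformly before
    its event time. Returns (expression genes x samples, clinical table).
    """
    if not sig_genes:
        raise ValueError("signature is empty; cannot simulate a scored cohort")
    rng = cfg.rng("cohort")
    n = cfg.n_cohort_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    factor = rng.normal(0.0, 1.0, size=n)
    loading = 0.7
    sig_expr = (loading * factor
                + math.sqrt(1 - loading**2) * rng.normal(0.0, 1.0, size=(len(sig_genes), n)))
    bg_genes = [f"BG{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    bg_expr = rng.normal(0.0, 1.0, size=(len(bg_genes), n))
    expr = pd.DataFrame(
        np.vstack([sig_expr, bg_expr]), index=sig_genes + bg_genes, columns=samples
    )
    expr.index.name = "gene_id"

    score = sig_expr.mean(axis=0)
    base_rate = math.log(2.0) / cfg.baseline_median_survival
    rate = base_rate * np.exp(cfg.hazard_beta * score)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < cfg.censor_rate
    t_obs = np.where(censored, t_event * rng.random(n), t_event)
    clinical = pd.DataFrame(
        {"time": np.round(t_obs, 4), "event": (~censored).astype(int)},
        index=pd.Index(samples, name="sample"),
    )
    return expr, clinical


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write every pipeline input; returns a path manifest.

    The cohort written here is scored against the *planted* B-unique gene
    class, which stands in for a derived signature when the generator is
    run standalone; the full pipeline regenerates the cohort from the
    signature it actually derives.
    """
    from .enrichment import write_gmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = generate_genome_annotation(cfg)
    peaks_a, peaks_b, truth = generate_condition_peaks(cfg, ann)
    counts, design = generate_counts(cfg, ann, truth)
    motifs_a, motifs_b, _ = generate_motif_tables(cfg)
    network = generate_regulator_network(cfg, truth)
    gene_sets = generate_gene_sets(cfg, truth)
    expr, clinical = generate_cohort(cfg, sorted(truth.planted_unique_genes_B))

    paths = {k: outdir / v for k, v in {
        "annotation": "annotation.tsv", "peaks_a": "peaks_A.bed",
        "peaks_b": "peaks_B.bed", "counts": "counts.tsv", "design": "design.tsv",
        "motifs_a": "motifs_A.tsv", "motifs_b": "motifs_B.tsv",
        "network": "network.tsv", "gene_sets": "gene_sets.gmt",
        "ezh2_regulated": "ezh2_regulated.gmt", "cohort_expr": "cohort_expression.tsv",
        "clinical": "clinical.tsv", "truth": "truth.json",
    }.items()}

    ann.to_tsv(paths["annotation"])
    peaks_a.to_bed(paths["peaks_a"])
    peaks_b.to_bed(paths["peaks_b"])
    counts.to_csv(paths["counts"], sep="\t")
    design.reset_index().to_csv(paths["design"], sep="\t", index=False)
    for p, tab in ((paths["motifs_a"], motifs_a), (paths["motifs_b"], motifs_b)):
        tab.reset_index().to_csv(p, sep="\t", index=False)
    network.to_csv(paths["network"], sep="\t", index=False)
    write_gmt(gene_sets, paths["gene_sets"])
    write_gmt({"EZH2_REGULATED": truth.planted_ezh2_regulated}, paths["ezh2_regulated"])
    expr.to_csv(paths["cohort_expr"], sep="\t")
    clinical.reset_index().to_csv(paths["clinical"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
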