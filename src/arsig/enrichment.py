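"""Gene-set and motif enrichment.

Three flavours of enrichment used when interpreting condition-specific
regulation:

* :func:`preranked_gsea` — pre-ranked gene-set enrichment: the classic
  weighted running-sum enrichment score with a gene-label permutation
  null, NES normalized by the same-sign null mean;
* :func:`overrepresentation_test` — one-sided Fisher exact tests of a
  query gene set against a collection over a fixed universe (used both for
  GO-style pathway enrichment and for regulator-target enrichment against
  a ChIP-compendium-style regulator -> target network);
* :func:`motif_rank_difference` — the waterfall comparison of motif
  z-score ranks between two conditions.

All permutation machinery is seeded and fully deterministic; rank ties
are broken lexicographically by name.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_fdr

__all__ = [
    "make_ranked_list",
    "preranked_gsea",
    "overrepresentation_test",
    "motif_rank_difference",
    "read_gmt",
    "write_gmt",
    "read_motif_table",
    "read_regulator_network",
    "network_to_collection",
]


def make_ranked_list(metric: pd.Series) -> pd.Series:
    """Validate and sort a gene -> metric series into a ranked list
    (descending metric, ties broken by gene name ascending)."""
    if metric.index.duplicated().any():
        dupes = metric.index[metric.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate genes in ranked list: {dupes[:5]}")
    if not np.isfinite(metric.to_numpy(dtype=float)).all():
        raise ValueError("ranking metric must be finite")
    df = metric.rename("metric").rename_axis("gene").reset_index()
    df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="mergesort")
    return df.set_index("gene")["metric"]


def _running_es(metric: np.ndarray, hits: np.ndarray, weight: int) -> float:
    """Signed max-deviation of the weighted running sum.

    Hit steps are proportional to |metric|^weight (normalized to sum 1
    over hits); miss steps are -1/(N - n). With weight 0 every hit steps
    1/n.
    """
    n_hit = int(hits.sum())
    n = metric.size
    if n_hit == 0 or n_hit == n:
        return 0.0
    w = np.abs(metric) ** weight
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all in-set metrics are exactly zero
        hit_w = hits.astype(float)
        total = float(n_hit)
    steps = hit_w / total - (~hits) / (n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(
    ranked: pd.Series,
    sets: dict[str, set[str]],
    n_perm: int = 1000,
    weight: int = 1,
    min_size: int = 5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a collection of gene sets.

    For each set, the enrichment score (ES) is the signed maximum deviation
    of the running sum over the ranked list. The null distribution comes
    from ``n_perm`` random same-size gene sets (gene-label permutation);
    NES = ES / mean(|null ES| of the same sign) and the two-sided p-value
    is the matching-sign null tail ``(1 + #{|null| >= |ES|}) / (1 + #same
    sign)``. BH FDR is computed over the evaluated sets. Sets with fewer
    than ``min_size`` members present in the ranking are reported with NA
    statistics.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = make_ranked_list(ranked)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    metric = ranked.to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    n = genes.size

    rows = []
    for name in sorted(sets):
        members = sets[name]
        idx = np.array(sorted(pos[g] for g in members if g in pos), dtype=int)
        k = idx.size
        if k < min_size:
            rows.append({"set": name, "size": k, "es": np.nan, "nes": np.nan, "p": np.nan})
            continue
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es = _running_es(metric, hits, weight)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm_hits = np.zeros(n, dtype=bool)
            perm_hits[rng.choice(n, size=k, replace=False)] = True
            null[b] = _running_es(metric, perm_hits, weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size:
            nes = es / np.abs(same_sign).mean()
            p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
        else:
            nes = np.nan
            p = 1.0 / (1 + n_perm)
        rows.append({"set": name, "size": k, "es": es, "nes": nes, "p": p})

    table = pd.DataFrame(rows).set_index("set")
    tested = table["p"].notna()
    fdr = np.full(len(table), np.nan)
    fdr[tested.to_numpy()] = adjust_fdr(table.loc[tested, "p"].to_numpy())
    table["fdr"] = fdr
    return table


def overrepresentation_test(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation of ``query`` in each set.

    Each set is intersected with the universe before testing; the 2x2
    table is (in-query x in-set) over the universe, with the enrichment
    alternative (greater). The odds ratio uses the Haldane correction
    (+0.5 per cell) when any cell is zero. BH FDR over the tested sets;
    any significance filter (e.g. fdr < 0.05) belongs to the reporting
    layer, not here.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)
        raise ValueError(f"query genes outside universe: {extra[:5]}")
    n_u = len(universe)
    n_q = len(query)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        a = len(query & members)
        b = n_q - a
        c = len(members) - a
        d = n_u - n_q - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            odds = (a * d) / (b * c)
        rows.append({"set": name, "overlap": a, "set_size": len(members),
                     "odds_ratio": odds, "p": float(p)})
    if not rows:
        return pd.DataFrame(
            columns=["overlap", "set_size", "odds_ratio", "p", "fdr"]
        ).rename_axis("set")
    table = pd.DataFrame(rows).set_index("set")
    table["fdr"] = adjust_fdr(table["p"].to_numpy())
    return table


def motif_rank_difference(a: pd.Series, b: pd.Series) -> pd.DataFrame:
    """Waterfall table of motif rank shifts between two conditions.

    Motifs are ranked within each table by descending z-score (rank 1 =
    most enriched; ties broken by motif name); delta_rank = rank_a -
    rank_b, so a motif gaining enrichment in B gets a positive delta. The
    inner join of the two motif universes is used; disjoint universes are
    refused. Output is in waterfall order: descending delta_rank (largest
    B-ward shift first), ties by motif name.
    """
    for t, lab in ((a, "A"), (b, "B")):
        if t.index.duplicated().any():
            raise ValueError(f"duplicate motif names in table {lab}")
        if not np.isfinite(t.to_numpy(dtype=float)).all():
            raise ValueError(f"non-finite z-scores in table {lab}")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("motif universes are disjoint; nothing to compare")

    def ranks(z: pd.Series) -> pd.Series:
        df = z.loc[shared].rename("z").rename_axis("motif").reset_index()
        df = df.sort_values(["z", "motif"], ascending=[False, True], kind="mergesort")
        df["rank"] = np.arange(1, len(df) + 1)
        return df.set_index("motif")["rank"]

    ra, rb = ranks(a), ranks(b)
    out = pd.DataFrame(
        {"zscore_a": a.loc[shared], "zscore_b": b.loc[shared],
         "rank_a": ra.loc[shared], "rank_b": rb.loc[shared]}
    )
    out["delta_rank"] = out["rank_a"] - out["rank_b"]
    out = out.iloc[np.lexsort((out.index.to_numpy(), -out["delta_rank"].to_numpy()))]
    out.index.name = "motif"
    return out


# -- readers/writers -------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, tab-separated (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            if parts[0] in sets:
                raise ValueError(f"duplicate set name in GMT: {parts[0]}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


def read_motif_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"motif": str})
    if df["motif"].duplicated().any():
        raise ValueError(f"duplicate motif names in {path}")
    return df.set_index("motif")["zscore"]


def read_regulator_network(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def network_to_collection(network: pd.DataFrame) -> dict[str, set[str]]:
    """Regulator -> target edge list to a {regulator: targets} collection."""
    if len(network) == 0:
        return {}
    return {
        reg: set(sub["target"]) for reg, sub in network.groupby("regulator", sort=True)
    }
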