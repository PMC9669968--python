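"""Condition-unique and co-target gene signatures, scoring, comparisons.

The central derivation takes two condition contrasts (each with its own
DE table and direct-target calls against the matched cistrome) and
produces condition-unique signatures in three steps:

  (i)   per condition, keep genes passing fold-change > fc_thresh and
        FDR < fdr_thresh (either direction) that are direct binding
        targets;
  (ii)  overlap the two filtered sets and keep the genes unique to each
        condition;
  (iii) keep a unique gene only if its folded linear fold-change in its
        own condition exceeds the other condition's by a factor
        > diff_ratio.

Step iii's "fold-change difference" is interpreted as a *ratio* of folded
fold-changes, max(fc, 1/fc), which is dimensionless and symmetric for up-
and down-regulated genes; an arithmetic-difference reading is available
via ``mode="difference"``. Genes absent from one condition's DE table are
treated as neutral there (fc = 1, fdr = 1) so uniqueness is decidable for
every gene.

A co-target signature intersects one condition's up-/down-regulated
direct targets with an externally derived regulated gene set (e.g. genes
responsive to knockdown of a second regulator).

Per-sample signature scores default to the combined-z method (per-gene
z-score across samples, averaged over signature genes), matching a scorer
fed with z-scores centred and scaled across samples; a rank-based ssGSEA
variant is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import classify_de
from .integration import target_genes

__all__ = [
    "SignatureDefinition",
    "derive_unique_signatures",
    "derive_cotarget_signature",
    "score_signature",
    "compare_groups",
]


@dataclass
class SignatureDefinition:
    """A named gene list with provenance and a derivation-parameter snapshot."""

    name: str
    genes: list[str]
    provenance: str = "external"  # A-unique | B-unique | co-target-up | co-target-down | external
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> set[str]:
        return set(self.genes)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "provenance": self.provenance,
                 "genes": self.genes, "params": self.params},
                fh, indent=2, default=str,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureDefinition":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["name"], d["genes"], d.get("provenance", "external"), d.get("params", {}))


def _folded_fc(de: pd.DataFrame, gene: str) -> float:
    """Linear fold-change folded to the >= 1 scale; neutral if absent."""
    if gene not in de.index:
        return 1.0
    fc = 2.0 ** float(de.loc[gene, "log2fc"])
    return max(fc, 1.0 / fc)


def derive_unique_signatures(
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    targets_a: pd.DataFrame,
    targets_b: pd.DataFrame,
    fc_thresh: float = 1.5,
    fdr_thresh: float = 0.05,
    diff_ratio: float = 1.5,
    mode: str = "ratio",
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[SignatureDefinition, SignatureDefinition]:
    """Three-step condition-unique signature derivation (see module docs).

    ``targets_a``/``targets_b`` are direct-target call tables from
    :func:`arsig.integration.call_direct_targets`. Returns one signature
    per condition; each carries the intermediate step-i and step-ii sets
    in ``params`` for provenance.
    """
    if mode not in {"ratio", "difference"}:
        raise ValueError("mode must be 'ratio' or 'difference'")

    def step_i(de: pd.DataFrame, targets: pd.DataFrame) -> set[str]:
        sets = classify_de(de, fc_thresh, fdr_thresh)
        return (sets["up"] | sets["down"]) & target_genes(targets)

    s_a = step_i(de_a, targets_a)
    s_b = step_i(de_b, targets_b)
    u_a = s_a - s_b
    u_b = s_b - s_a

    def step_iii(unique: set[str], de_own: pd.DataFrame, de_other: pd.DataFrame) -> list[str]:
        kept = []
        for g in sorted(unique):
            own, other = _folded_fc(de_own, g), _folded_fc(de_other, g)
            stat = own / other if mode == "ratio" else own - other
            if stat > diff_ratio:
                kept.append(g)
        return kept

    params = {
        "fc_thresh": fc_thresh, "fdr_thresh": fdr_thresh,
        "diff_ratio": diff_ratio, "mode": mode,
    }
    sig_a = SignatureDefinition(
        name=f"{labels[0]}_unique",
        genes=step_iii(u_a, de_a, de_b),
        provenance="A-unique",
        params={**params, "step_i": sorted(s_a), "step_ii": sorted(u_a)},
    )
    sig_b = SignatureDefinition(
        name=f"{labels[1]}_unique",
        genes=step_iii(u_b, de_b, de_a),
        provenance="B-unique",
        params={**params, "step_i": sorted(s_b), "step_ii": sorted(u_b)},
    )
    assert not (sig_a.gene_set & sig_b.gene_set)
    return sig_a, sig_b


def derive_cotarget_signature(
    up_genes: set[str],
    down_genes: set[str],
    external_regulated: set[str],
    labels: tuple[str, str] = ("cotarget_up", "cotarget_down"),
) -> tuple[SignatureDefinition, SignatureDefinition]:
    """Intersect a condition's up-/down-regulated direct targets with an
    external regulated gene set, yielding up- and down- co-target
    signatures whose sizes sum to the full intersection."""
    if up_genes & down_genes:
        raise ValueError("up and down gene sets must be disjoint")
    up = sorted(up_genes & external_regulated)
    down = sorted(down_genes & external_regulated)
    return (
        SignatureDefinition(labels[0], up, provenance="co-target-up"),
        SignatureDefinition(labels[1], down, provenance="co-target-down"),
    )


def score_signature(
    expr: pd.DataFrame,
    sig: SignatureDefinition,
    method: str = "combined_z",
    ssgsea_weight: float = 0.25,
) -> pd.Series:
    """Per-sample signature score over an expression matrix (genes x samples).

    combined_z (default): z-score each gene across samples (zero-variance
    genes get z = 0), then average the z of signature genes per sample.
    ssgsea: per sample, rank all genes by expression and take the summed
    difference of the weighted in-set vs uniform out-set running ECDFs.
    Missing signature genes are recorded in ``result.attrs["missing_genes"]``;
    if none are present the call is refused with a membership report.
    """
    if expr.shape[1] < 3:
        raise ValueError("need >= 3 samples to score a signature")
    present = [g for g in sig.genes if g in expr.index]
    missing = [g for g in sig.genes if g not in expr.index]
    if not present:
        raise ValueError(
            f"no genes of signature {sig.name!r} found in the expression matrix "
            f"({len(missing)} missing, e.g. {missing[:5]})"
        )
    if method == "combined_z":
        mat = expr.to_numpy(dtype=float)
        mu = mat.mean(axis=1, keepdims=True)
        sd = mat.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mat - mu) / sd
        z = np.where(np.isfinite(z), z, 0.0)  # constant genes contribute 0
        zdf = pd.DataFrame(z, index=expr.index, columns=expr.columns)
        scores = zdf.loc[present].mean(axis=0)
    elif method == "ssgsea":
        scores = pd.Series(
            {s: _ssgsea_one(expr[s], set(present), ssgsea_weight) for s in expr.columns}
        )
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    scores.name = sig.name
    scores.attrs["missing_genes"] = missing
    return scores


def _ssgsea_one(col: pd.Series, members: set[str], weight: float) -> float:
    order = col.rename("v").rename_axis("gene").reset_index()
    order = order.sort_values(["v", "gene"], ascending=[False, True], kind="mergesort")
    genes = order["gene"].to_numpy()
    n = genes.size
    hits = np.isin(genes, list(members))
    ranks = np.arange(n, 0, -1, dtype=float)  # top gene gets the largest weight
    w = np.where(hits, ranks**weight, 0.0)
    p_in = np.cumsum(w) / w.sum()
    n_out = n - hits.sum()
    p_out = np.cumsum(~hits) / n_out if n_out else np.zeros(n)
    return float((p_in - p_out).sum() / n)


def compare_groups(
    scores: pd.Series,
    groups: pd.Series,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparison of signature scores per group pair.

    Exact enumeration when both groups have n <= 10 and no ties span the
    groups; otherwise the normal approximation with tie correction.
    """
    groups = groups.loc[scores.index]
    if pairs is None:
        pairs = list(combinations(sorted(groups.unique()), 2))
    rows = []
    for g1, g2 in pairs:
        x = scores[groups == g1].to_numpy(dtype=float)
        y = scores[groups == g2].to_numpy(dtype=float)
        method = "exact" if (len(x) <= 10 and len(y) <= 10) else "asymptotic"
        try:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:  # exact method refuses ties; fall back
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append({"group1": g1, "group2": g2, "n1": len(x), "n2": len(y),
                     "statistic": float(res.statistic), "p": float(res.pvalue)})
    return pd.DataFrame(rows)
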