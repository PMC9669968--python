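"""End-to-end pipeline: simulate -> DE -> cistrome -> integration ->
signatures -> co-targets -> enrichment -> scoring -> survival.

Every stage writes flat TSV/JSON artifacts into the run directory so any
stage can be rerun or inspected independently, and a manifest records the
config hash, seed and a SHA-256 digest of every artifact; rerunning with
the same config and seed reproduces all artifacts byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cistrome, diffexpr, enrichment, integration, signatures, survival
from .simulate import SimConfig, SyntheticTruth, generate_cohort, simulate_all

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("arsig")


@dataclass
class PipelineConfig:
    """All thresholds and paths driving a pipeline run.

    With ``simulate=True`` (default) inputs are generated into the run
    directory from ``sim``; otherwise the ``inputs`` mapping must name the
    input files (annotation, peaks_a, peaks_b, counts, design, motifs_a,
    motifs_b, network, gene_sets, ezh2_regulated, and optionally
    cohort_expr + clinical).
    """

    seed: int = 0
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    inputs: dict = field(default_factory=dict)
    condition_labels: tuple[str, str] = ("A", "B")
    fc_thresh: float = 1.5
    fdr_thresh: float = 0.05
    diff_ratio: float = 1.5
    rp_window: int = 100_000
    top_n_peaks: int = 5000
    top_frac: float = 0.25
    max_gap: int = 0
    promoter_window: int = 3000
    scoring_method: str = "combined_z"
    n_perm: int = 1000
    run_enrichment: bool = True
    run_survival: bool = True

    def __post_init__(self) -> None:
        for name in ("fc_thresh", "fdr_thresh", "diff_ratio", "top_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.simulate:
            # one seed drives everything, including the generator
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "sim" in raw and isinstance(raw["sim"], dict):
            raw["sim"] = SimConfig(**raw["sim"])
        if "condition_labels" in raw:
            raw["condition_labels"] = tuple(raw["condition_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["condition_labels"] = list(d["condition_labels"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc_type is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
        else:
            log.error("stage %s: FAILED after %.2fs: %s", self.name, dt, exc)
        return False


def _precision_recall(derived: set[str], planted: set[str]) -> dict:
    tp = len(derived & planted)
    precision = tp / len(derived) if derived else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return {"n_derived": len(derived), "n_planted": len(planted),
            "precision": precision, "recall": recall}


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing artifacts + manifest + report into ``outdir``.

    Returns the report dict. Any stage failure propagates with the stage
    name in the log; artifacts written before the failure are retained.
    """
    if not logging.getLogger().handlers and not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(levelname)s %(name)s: %(message)s")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "config_hash": cfg.digest()}
    lab_a, lab_b = cfg.condition_labels

    # -- inputs ------------------------------------------------------------
    with _StageTimer("simulate" if cfg.simulate else "load"):
        if cfg.simulate:
            paths = simulate_all(cfg.sim, outdir / "inputs")
        else:
            paths = {k: Path(v) for k, v in cfg.inputs.items()}
            required = ["annotation", "peaks_a", "peaks_b", "counts", "design",
                        "network", "gene_sets", "ezh2_regulated"]
            for key in required:
                if key not in paths:
                    raise ValueError(f"inputs mapping missing required key {key!r}")
                if not paths[key].exists():
                    raise FileNotFoundError(
                        f"input file for {key!r} not found: {paths[key]}")
        ann = cistrome.GenomeAnnotation.from_tsv(paths["annotation"])
        peaks_a = cistrome.PeakSet.from_bed(paths["peaks_a"], lab_a)
        peaks_b = cistrome.PeakSet.from_bed(paths["peaks_b"], lab_b)
        counts = diffexpr.read_counts(paths["counts"])
        design = diffexpr.read_design(paths["design"])
        truth = (SyntheticTruth.from_json(paths["truth"])
                 if "truth" in paths and Path(paths["truth"]).exists() else None)

    # -- differential expression ------------------------------------------
    with _StageTimer("diffexpr"):
        de = {}
        for lab, group in ((lab_a, "A"), (lab_b, "B")):
            de[lab] = diffexpr.test_differential_expression(
                counts, design, (group, "vehicle"), cfg.fc_thresh, cfg.fdr_thresh)
            diffexpr.write_de_table(de[lab], outdir / f"de_{lab}.tsv")

    # -- cistrome ----------------------------------------------------------
    with _StageTimer("cistrome"):
        venn = cistrome.partition_peak_sets(peaks_a, peaks_b, cfg.max_gap)
        venn.write(outdir / "venn")
        report["venn_counts"] = venn.counts
        for lab, p in ((lab_a, peaks_a), (lab_b, peaks_b)):
            dist = cistrome.annotate_genomic_distribution(p, ann, cfg.promoter_window)
            dist.to_csv(outdir / f"genomic_distribution_{lab}.tsv", sep="\t", index=False)
            top = cistrome.select_top_peaks(p, cfg.top_n_peaks)
            top.to_bed(outdir / f"top_peaks_{lab}.bed")

    # -- integration -------------------------------------------------------
    with _StageTimer("integration"):
        rp, targets = {}, {}
        for lab, p in ((lab_a, peaks_a), (lab_b, peaks_b)):
            rp[lab] = integration.regulatory_potential(p, ann, cfg.rp_window)
            rp[lab].reset_index().to_csv(outdir / f"rp_{lab}.tsv", sep="\t", index=False)
            targets[lab] = integration.call_direct_targets(
                rp[lab], de[lab], cfg.fc_thresh, cfg.fdr_thresh)
            targets[lab].reset_index().to_csv(
                outdir / f"targets_{lab}.tsv", sep="\t", index=False)
        report["activation_test"] = {}
        for lab in (lab_a, lab_b):
            try:
                act = integration.activation_function_test(
                    rp[lab], de[lab], cfg.fc_thresh, cfg.fdr_thresh)
                act["curves"].to_csv(
                    outdir / f"activation_curves_{lab}.tsv", sep="\t", index=False)
                report["activation_test"][lab] = {
                    "up_p": act["up_p"], "down_p": act["down_p"]}
            except ValueError as e:
                log.warning("activation test (%s) skipped: %s", lab, e)
                report["activation_test"][lab] = {"skipped": str(e)}

    # -- signatures --------------------------------------------------------
    with _StageTimer("signatures"):
        sig_a, sig_b = signatures.derive_unique_signatures(
            de[lab_a], de[lab_b], targets[lab_a], targets[lab_b],
            cfg.fc_thresh, cfg.fdr_thresh, cfg.diff_ratio,
            labels=(lab_a, lab_b))
        for sig in (sig_a, sig_b):
            sig.to_json(outdir / f"signature_{sig.name}.json")
        enrichment.write_gmt(
            {sig_a.name: sig_a.gene_set, sig_b.name: sig_b.gene_set},
            outdir / "signatures.gmt")
        report["signature_sizes"] = {sig_a.name: len(sig_a), sig_b.name: len(sig_b)}
        if truth is not None:
            report["recovery"] = {
                lab_a: _precision_recall(sig_a.gene_set, truth.planted_unique_genes_A),
                lab_b: _precision_recall(sig_b.gene_set, truth.planted_unique_genes_B),
            }

    # -- co-target signature ----------------------------------------------
    with _StageTimer("cotarget"):
        ezh2_sets = enrichment.read_gmt(paths["ezh2_regulated"])
        external = set().union(*ezh2_sets.values()) if ezh2_sets else set()
        de_sets_b = diffexpr.classify_de(de[lab_b], cfg.fc_thresh, cfg.fdr_thresh)
        tgt_b = integration.target_genes(targets[lab_b])
        co_up, co_down = signatures.derive_cotarget_signature(
            de_sets_b["up"] & tgt_b, de_sets_b["down"] & tgt_b, external)
        for sig in (co_up, co_down):
            sig.to_json(outdir / f"signature_{sig.name}.json")
        report["cotarget_sizes"] = {"up": len(co_up), "down": len(co_down)}

    # -- enrichment --------------------------------------------------------
    if cfg.run_enrichment:
        with _StageTimer("enrichment"):
            gene_sets = enrichment.read_gmt(paths["gene_sets"])
            ranked = enrichment.make_ranked_list(de[lab_b]["log2fc"])
            gsea = enrichment.preranked_gsea(
                ranked, gene_sets, n_perm=cfg.n_perm, seed=cfg.seed)
            gsea.reset_index().to_csv(outdir / "gsea.tsv", sep="\t", index=False)

            network = enrichment.read_regulator_network(paths["network"])
            reg_sets = enrichment.network_to_collection(network)
            universe = set(de[lab_b].index)
            query = (de_sets_b["up"] | de_sets_b["down"]) & universe
            reg = enrichment.overrepresentation_test(query, reg_sets, universe)
            reg = reg.sort_values(["fdr", "p", "odds_ratio"],
                                  ascending=[True, True, False], kind="mergesort")
            reg.reset_index().to_csv(outdir / "regulator_enrichment.tsv",
                                     sep="\t", index=False)
            report["top_regulator"] = (
                {"set": reg.index[0], "fdr": float(reg["fdr"].iloc[0])}
                if len(reg) else None)

            if "motifs_a" in paths and "motifs_b" in paths:
                mot_a = enrichment.read_motif_table(paths["motifs_a"])
                mot_b = enrichment.read_motif_table(paths["motifs_b"])
                waterfall = enrichment.motif_rank_difference(mot_a, mot_b)
                waterfall.reset_index().to_csv(outdir / "motif_waterfall.tsv",
                                               sep="\t", index=False)

    # -- scoring + survival ------------------------------------------------
    if cfg.run_survival:
        with _StageTimer("survival"):
            score_sig = co_up if len(co_up) else sig_b
            if cfg.simulate:
                expr, clinical = generate_cohort(cfg.sim, score_sig.genes)
                expr.to_csv(outdir / "cohort_expression.tsv", sep="\t")
                clinical.reset_index().to_csv(outdir / "clinical.tsv",
                                              sep="\t", index=False)
            else:
                if "cohort_expr" not in paths or "clinical" not in paths:
                    raise ValueError(
                        "survival stage enabled but inputs lack "
                        "'cohort_expr'/'clinical' paths")
                for key in ("cohort_expr", "clinical"):
                    if not paths[key].exists():
                        raise FileNotFoundError(
                            f"input file for {key!r} not found: {paths[key]}")
                expr = diffexpr.read_counts(paths["cohort_expr"]).astype(float)
                clinical = survival.read_clinical(paths["clinical"])
            scores = signatures.score_signature(expr, score_sig, cfg.scoring_method)
            scores.rename("score").rename_axis("sample").reset_index().to_csv(
                outdir / "scores.tsv", sep="\t", index=False)
            cohort = clinical.join(scores.rename("score"))
            strat = survival.stratify_by_score(cohort, cfg.top_frac)
            for stratum in ("high", "low"):
                km = survival.kaplan_meier(strat[strat["stratum"] == stratum])
                km.to_csv(outdir / f"km_{stratum}.tsv", sep="\t", index=False)
            lr = survival.score_stratified_logrank(cohort, cfg.top_frac)
            _write_json(lr, outdir / "logrank.json")
            report["survival"] = lr

    # -- manifest ----------------------------------------------------------
    _write_json(report, outdir / "report.json")
    artifacts = sorted(
        p for p in outdir.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.digest(),
        "artifacts": {str(p.relative_to(outdir)): _sha256(p) for p in artifacts},
    }
    _write_json(manifest, outdir / "manifest.json")
    for rel in manifest["artifacts"]:
        assert (outdir / rel).stat().st_size > 0, f"empty artifact {rel}"
    return report
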