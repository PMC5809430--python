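"""End-to-end orchestration: extract -> enrich -> motif -> classify.

`run_all` ties the stages together from a RunConfig, writes every
stage's TSV outputs plus a JSON run report, and is deterministic given
the configured seeds.  `rank_order_report` reproduces the rank-order
listing of significantly cleaved peptides (ascending p_FDR, ties broken
by |log2fc| then lexicographically) used to place a query peptide such
as the native VWF73 interval.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as clf
from . import enrichment, motif
from .readproc import ExtractionTemplate, PeptideCountTable, SampleSpec, tally_peptides

logger = logging.getLogger("phageprofiler")


@dataclass
class Thresholds:
    min_total: int = 4
    alpha: float = 0.05
    min_bin: int = 10
    tol: float = 0.001
    max_features: int = 20


@dataclass
class RunConfig:
    template: ExtractionTemplate
    samples: list[SampleSpec]
    outdir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    anchor_residue: str = "R"
    anchor_mode: str = "center_most"
    classify_mode: str = "positional"
    seed: int = 0

    def validate(self) -> None:
        roles = {s.role for s in self.samples}
        if not {"selected", "unselected"} <= roles:
            raise ValueError("need at least one selected and one unselected sample")
        for s in self.samples:
            for path in (s.r1, s.r2):
                if not os.path.exists(path):
                    raise FileNotFoundError(path)


def rank_order_report(records: pd.DataFrame, query: str | None = None):
    """Rank cleaved peptides by ascending p_fdr (|log2fc| desc, then lexicographic).

    Returns ``(ranked DataFrame, rank of query or None)``; a query that is
    not significantly cleaved is reported as absent (None).
    """
    cleaved = records.loc[records["label"] == "cleaved"].copy()
    cleaved["_abs_fc"] = cleaved["log2fc"].abs()
    cleaved = cleaved.sort_values(
        by=["p_fdr", "_abs_fc", "peptide"]
        if "peptide" in cleaved.columns
        else ["p_fdr", "_abs_fc"],
        ascending=[True, False] + ([True] if "peptide" in cleaved.columns else []),
    )
    if "peptide" not in cleaved.columns:
        cleaved = (
            cleaved.rename_axis("peptide")
            .reset_index()
            .sort_values(["p_fdr", "_abs_fc", "peptide"], ascending=[True, False, True])
        )
    cleaved = cleaved.drop(columns="_abs_fc").reset_index(drop=True)
    cleaved.insert(0, "rank", np.arange(1, len(cleaved) + 1))
    rank = None
    if query is not None:
        hit = cleaved.loc[cleaved["peptide"] == query, "rank"]
        rank = int(hit.iloc[0]) if len(hit) else None
    return cleaved, rank


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline and write all outputs under config.outdir."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)  # noqa: E731
    th = config.thresholds
    bundle: dict = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("extract")
        table, qc = tally_peptides(config.samples, config.template)
        table.to_tsv(out("counts.tsv"), out("design.tsv"))
        with open(out("qc.json"), "w") as fh:
            json.dump({k: v.to_dict() for k, v in qc.items()}, fh, indent=2)
        bundle["table"], bundle["qc"] = table, qc
    except Exception as exc:
        raise RuntimeError(f"[extract] {exc}") from exc

    try:
        stage("enrich")
        records = enrichment.run_enrichment(
            table, alpha=th.alpha, min_total=th.min_total
        )
        records.rename_axis("peptide").to_csv(out("enrichment.tsv"), sep="\t")
        bundle["records"] = records
    except Exception as exc:
        raise RuntimeError(f"[enrich] {exc}") from exc

    try:
        stage("motif")
        cleaved = list(records.index[records["label"] == "cleaved"])
        depleted = list(records.index[records["label"] == "depleted"])
        if cleaved and depleted:
            pfm_c = motif.position_frequencies(cleaved)
            pfm_d = motif.position_frequencies(depleted)
            pfm_c.to_tsv(out("pfm_cleaved.tsv"))
            pfm_d.to_tsv(out("pfm_depleted.tsv"))
            logo = motif.differential_logo(pfm_c, pfm_d)
            logo.to_tsv(out("differential_logo.tsv"))
            bundle["logo"] = logo
            aligned_c = motif.align_on_anchor(cleaved, config.anchor_residue, config.anchor_mode)
            aligned_d = motif.align_on_anchor(depleted, config.anchor_residue, config.anchor_mode)
            if aligned_c.peptides and aligned_d.peptides:
                a_logo = motif.differential_logo(
                    motif.position_frequencies(aligned_c),
                    motif.position_frequencies(aligned_d),
                )
                a_logo.to_tsv(out("differential_logo_anchored.tsv"))
                bundle["anchored_logo"] = a_logo
        profiles, bins = motif.pvalue_binned_profiles(records, min_bin=th.min_bin)
        profiles.join(bins).to_csv(out("binned_profiles.tsv"), sep="\t")
        props = motif.aa_proportion_comparison(records)
        props.to_csv(out("aa_proportions.tsv"), sep="\t")
        bundle["proportions"] = props
    except Exception as exc:
        raise RuntimeError(f"[motif] {exc}") from exc

    try:
        stage("classify")
        rng = np.random.default_rng(config.seed)
        n_pos = int((records["label"] == "cleaved").sum())
        n_neutral = int((records["label"] == "neutral").sum())
        if n_pos >= 2 and n_neutral >= n_pos:
            positives = list(records.index[records["label"] == "cleaved"])
            negatives = clf.sample_negatives(records, n_pos, rng)
            result = {}
            for mode in ("global", "positional"):
                feats = clf.build_features(positives, negatives, mode=mode)
                sw = clf.forward_stepwise(
                    feats, tol=th.tol, max_features=th.max_features
                )
                sw.to_frame().to_csv(out(f"stepwise_{mode}.tsv"), sep="\t", index=False)
                result[mode] = sw
            bundle["stepwise"] = result
        else:
            logger.warning("too few cleaved/neutral peptides; classify skipped")
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc

    stage("report")
    ranked, _ = rank_order_report(records)
    ranked.head(200).to_csv(out("rank_order.tsv"), sep="\t", index=False)
    label_counts = records["label"].value_counts().to_dict()
    report = {
        "samples": {k: v.to_dict() for k, v in bundle["qc"].items()},
        "n_peptides_tested": int(len(records)),
        "labels": {k: int(label_counts.get(k, 0)) for k in enrichment.LABELS},
        "top_peptides": ranked.head(10)["peptide"].tolist() if len(ranked) else [],
    }
    if "stepwise" in bundle:
        report["stepwise"] = {
            mode: {
                "features": sw.features,
                "signs": sw.signs,
                "auroc_path": sw.auroc_path,
            }
            for mode, sw in bundle["stepwise"].items()
        }
    with open(out("run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    bundle["report"] = report
    bundle["ranked"] = ranked
    return bundle
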