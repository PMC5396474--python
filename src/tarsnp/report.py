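"""End-to-end screen orchestration and tabular reports.

``run_screen`` wires the stages together: load references -> cut allele
windows -> score both alleles against every miRNA -> diff/classify ->
rank -> drug/network annotation -> TSV reports. Every knob lives in one
YAML config; relative paths resolve against the config file's directory.
"""

from __future__ import annotations

import csv
import logging
import os
from collections import Counter
from typing import Optional

import yaml

from .classify import TarSnpCall, is_tarsnp, make_call, rank_tarsnps
from .drug_network import (
    annotate_targets,
    load_drug_map,
    load_pathways,
    load_ppi,
    predict_response_direction,
)
from .reference_io import WILD, VARIANT, load_mirnas, load_snps, load_utrs, make_allele_windows
from .target_scoring import (
    EngineScoreProvider,
    EnergyModel,
    ScoreProvider,
    SeedRules,
    TableScoreProvider,
)

logger = logging.getLogger(__name__)

CALL_COLUMNS = [
    "snp_id", "gene_id", "mirna_id", "wild_energy", "mutation_energy",
    "ddG", "effect_class", "norm_ddG",
]
ANNOTATION_COLUMNS = [
    "drug", "snp_id", "gene_id", "mirna_id", "ddG", "effect_class",
    "target_type", "anchor_target", "path_length", "pathway_id",
    "response_direction",
]

DEFAULTS = {
    "flank": 30,
    "accessibility": False,
    "min_abs_diff": 0.0,
    "pathway_clique": False,
    "out_dir": "results",
}


def _fmt(value) -> str:
    """Numbers at up to 6 significant digits; absent values as 'None'."""
    if value is None:
        return "None"
    if isinstance(value, float):
        return f"{value:.6g}"
    return str(value)


def load_config(path: str) -> dict:
    """Read the screen config, filling defaults and resolving paths."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(path))
    merged = {**DEFAULTS, **config}
    for key in ("fasta", "bed", "vcf", "mirna_fasta", "drug_map", "ppi",
                "pathway_members", "pathway_edges", "score_table", "out_dir"):
        if merged.get(key) and not os.path.isabs(merged[key]):
            merged[key] = os.path.join(base, merged[key])
    return merged


def write_calls_tsv(path: str, calls: list[TarSnpCall]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for c in calls:
            writer.writerow([
                c.snp_id, c.gene_id, c.mirna_id, _fmt(c.t_wt), _fmt(c.t_var),
                _fmt(c.diff), c.effect_class.value, _fmt(c.norm_diff),
            ])


def read_calls_tsv(path: str) -> list[TarSnpCall]:
    """Rebuild classified calls from a calls TSV (diff/class recomputed)."""
    calls = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            t_wt = None if row["wild_energy"] == "None" else float(row["wild_energy"])
            t_var = None if row["mutation_energy"] == "None" else float(row["mutation_energy"])
            call = make_call(row["snp_id"], row["gene_id"], row["mirna_id"], t_wt, t_var)
            if call is not None:
                calls.append(call)
    return calls


def classify_score_table(
    scores_path: str, out_path: Optional[str] = None, min_abs_diff: float = 0.0
) -> list[TarSnpCall]:
    """Score-table-only mode: pair wild/variant rows, diff, classify, rank.

    The input TSV needs columns snp_id, mirna_id, allele (wild|variant) and
    score (empty or 'None' = no predicted site); gene_id is optional.
    """
    pairs: dict[tuple[str, str, str], dict[str, Optional[float]]] = {}
    with open(scores_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            key = (row["snp_id"], row.get("gene_id", ""), row["mirna_id"])
            raw = (row.get("score") or "").strip()
            value = None if raw in ("", "None", "NA") else float(raw)
            pairs.setdefault(key, {})[row["allele"]] = value

    calls = []
    for (snp_id, gene_id, mirna_id), scores in pairs.items():
        call = make_call(
            snp_id, gene_id, mirna_id, scores.get(WILD), scores.get(VARIANT)
        )
        if call is not None and is_tarsnp(call, min_abs_diff):
            calls.append(call)
    ranked = rank_tarsnps(calls)
    if out_path:
        write_calls_tsv(out_path, ranked)
    return ranked


def write_annotations_tsv(path: str, calls: list[TarSnpCall], annotations) -> None:
    """One row per (annotation, call on the annotated gene), per-call
    response direction."""
    calls_by_gene: dict[str, list[TarSnpCall]] = {}
    for c in calls:
        calls_by_gene.setdefault(c.gene_id, []).append(c)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for ann in annotations:
            for c in calls_by_gene.get(ann.gene_id, []):
                writer.writerow([
                    ann.drug_id, c.snp_id, c.gene_id, c.mirna_id, _fmt(c.diff),
                    c.effect_class.value, ann.target_type, ann.anchor_target,
                    _fmt(ann.path_length), ann.pathway_id or "None",
                    predict_response_direction(c.effect_class),
                ])


def annotate_calls(calls: list[TarSnpCall], config: dict):
    """Run the drug/network annotation stages configured in ``config``."""
    drug_map = load_drug_map(config["drug_map"])
    ppi = load_ppi(config["ppi"]) if config.get("ppi") else None
    pathways = None
    if config.get("pathway_members"):
        pathways = load_pathways(
            config["pathway_members"],
            edges_path=config.get("pathway_edges"),
            clique_if_no_edges=bool(config.get("pathway_clique")),
        )
    return annotate_targets(calls, drug_map, ppi, pathways)


def run_screen(config: dict) -> dict[str, str]:
    """Execute the full screen; returns paths of the written reports."""
    out_dir = config["out_dir"]
    os.makedirs(out_dir, exist_ok=True)

    logger.info("loading references")
    utrs = load_utrs(config["bed"], config["fasta"])
    mirnas = load_mirnas(config["mirna_fasta"])
    snps = load_snps(config["vcf"], utrs)
    utr_by_gene = {u.gene_id: u for u in utrs}
    logger.info("loaded %d UTRs, %d miRNAs, %d UTR SNPs", len(utrs), len(mirnas), len(snps))

    provider: ScoreProvider
    if config.get("score_table"):
        provider = TableScoreProvider.from_tsv(config["score_table"])
        logger.info("scoring from precomputed table %s", config["score_table"])
    else:
        provider = EngineScoreProvider(
            model=EnergyModel(accessibility_enabled=bool(config.get("accessibility"))),
            rules=SeedRules(),
        )

    calls: list[TarSnpCall] = []
    score_rows = []
    n_windows = 0
    for snp in snps:
        wild, variant = make_allele_windows(
            snp, utr_by_gene[snp.gene_id], flank=int(config["flank"])
        )
        n_windows += 2
        for mirna in mirnas:
            t_wt = provider.score(snp.snp_id, mirna.mirna_id, WILD, wild, mirna)
            t_var = provider.score(snp.snp_id, mirna.mirna_id, VARIANT, variant, mirna)
            score_rows.append((snp.snp_id, mirna.mirna_id, WILD, _fmt(t_wt)))
            score_rows.append((snp.snp_id, mirna.mirna_id, VARIANT, _fmt(t_var)))
            if t_wt is None and t_var is None:
                continue
            call = make_call(snp.snp_id, snp.gene_id, mirna.mirna_id, t_wt, t_var)
            if call is not None and is_tarsnp(call, float(config["min_abs_diff"])):
                calls.append(call)
    ranked = rank_tarsnps(calls)
    by_class = Counter(c.effect_class.value for c in ranked)
    logger.info("built %d windows; %d tarSNP calls (%s)", n_windows, len(ranked),
                ", ".join(f"{k}={v}" for k, v in sorted(by_class.items())) or "none")

    paths = {"tarsnps": os.path.join(out_dir, "tarsnps.tsv"),
             "score_table": os.path.join(out_dir, "score_table.tsv")}
    write_calls_tsv(paths["tarsnps"], ranked)
    with open(paths["score_table"], "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_id", "mirna_id", "allele", "score"])
        writer.writerows(score_rows)

    if config.get("drug_map"):
        annotations = annotate_targets(
            ranked,
            load_drug_map(config["drug_map"]),
            load_ppi(config["ppi"]) if config.get("ppi") else None,
            load_pathways(
                config["pathway_members"],
                edges_path=config.get("pathway_edges"),
                clique_if_no_edges=bool(config.get("pathway_clique")),
            ) if config.get("pathway_members") else None,
        )
        by_type = Counter(a.target_type for a in annotations)
        logger.info("annotations: %s",
                    ", ".join(f"{k}={v}" for k, v in sorted(by_type.items())) or "none")
        paths["annotations"] = os.path.join(out_dir, "drug_annotations.tsv")
        write_annotations_tsv(paths["annotations"], ranked, annotations)

    return paths
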