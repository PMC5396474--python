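"""Mapping tarSNP genes onto drug targets, directly and through networks.

A drug-target gene that itself carries a tarSNP is a *direct* target. A
tarSNP gene that is a first neighbor of a direct target in the
protein-protein interaction network is a *PPIN-indirect* target; one that
shares a pathway with a direct target is a *pathway-indirect* target, with
the shortest-path distance inside that pathway's own edge set reported.

The predicted response direction follows the regulation logic: gain of
miRNA function downregulates the target protein, so gain classes predict
drug sensitivity; loss classes lift the repression, predicting resistance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from .classify import EffectClass, GAIN_CLASSES, LOSS_CLASSES, TarSnpCall, rank_tarsnps

DIRECT = "direct"
PPIN_INDIRECT = "ppin_indirect"
PATHWAY_INDIRECT = "pathway_indirect"

SENSITIVITY = "sensitivity"
RESISTANCE = "resistance"


@dataclass(frozen=True)
class PathwayGraph:
    """One pathway: members and the intra-pathway interaction graph."""

    pathway_id: str
    pathway_class: str  # metabolic | nonmetabolic
    members: frozenset
    graph: nx.Graph

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.pathway_id}: empty membership")
        stray = set(self.graph.nodes) - set(self.members)
        if stray:
            raise ValueError(
                f"pathway {self.pathway_id}: edges touch non-members {sorted(stray)}"
            )


@dataclass(frozen=True)
class TargetAnnotation:
    """A tarSNP gene's relation to one drug."""

    gene_id: str
    drug_id: str
    drug_name: str
    target_type: str  # direct | ppin_indirect | pathway_indirect
    path_length: Optional[int]
    anchor_target: str
    response_direction: str
    pathway_id: Optional[str] = None
    pathway_class: Optional[str] = None


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_drug_map(path: str) -> pd.DataFrame:
    """Drug-target TSV (drug_id, drug_name, gene_id), deduplicated."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"drug_id", "drug_name", "gene_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug map {path}: missing columns {sorted(missing)}")
    return df.drop_duplicates(subset=["drug_id", "gene_id"]).reset_index(drop=True)


def load_ppi(path: str) -> nx.Graph:
    """Undirected PPI edge list TSV (gene_a, gene_b); self-loops dropped."""
    graph = nx.Graph()
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            a, b = row["gene_a"], row["gene_b"]
            if a != b:
                graph.add_edge(a, b)
    return graph


def load_pathways(
    members_path: str,
    edges_path: Optional[str] = None,
    clique_if_no_edges: bool = True,
) -> list[PathwayGraph]:
    """Pathway membership TSV (+ optional intra-pathway edge TSV).

    When no edge table is supplied and ``clique_if_no_edges`` is set,
    co-membership is treated as a clique (every member pair at distance 1).
    """
    members: dict[str, set] = {}
    classes: dict[str, str] = {}
    with open(members_path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            pid = row["pathway_id"]
            members.setdefault(pid, set()).add(row["gene_id"])
            classes[pid] = row["pathway_class"]

    edges: dict[str, list[tuple[str, str]]] = {pid: [] for pid in members}
    if edges_path is not None:
        with open(edges_path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                edges.setdefault(row["pathway_id"], []).append(
                    (row["gene_a"], row["gene_b"])
                )

    pathways = []
    for pid in sorted(members):
        graph = nx.Graph()
        graph.add_nodes_from(sorted(members[pid]))
        if edges_path is not None:
            graph.add_edges_from(e for e in edges.get(pid, []) if e[0] != e[1])
        elif clique_if_no_edges:
            nodes = sorted(members[pid])
            graph.add_edges_from(
                (nodes[i], nodes[j])
                for i in range(len(nodes))
                for j in range(i + 1, len(nodes))
            )
        pathways.append(
            PathwayGraph(
                pathway_id=pid,
                pathway_class=classes[pid],
                members=frozenset(members[pid]),
                graph=graph,
            )
        )
    return pathways


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


def predict_response_direction(effect_class: EffectClass) -> str:
    """Gain of miRNA function -> sensitivity; loss -> resistance."""
    if effect_class in GAIN_CLASSES:
        return SENSITIVITY
    if effect_class in LOSS_CLASSES:
        return RESISTANCE
    raise ValueError(f"no response direction for effect class {effect_class}")


def _best_call_per_gene(calls: list[TarSnpCall]) -> dict[str, TarSnpCall]:
    """Top-priority call per gene (deterministic via rank_tarsnps)."""
    best: dict[str, TarSnpCall] = {}
    for call in rank_tarsnps(list(calls)):
        best.setdefault(call.gene_id, call)
    return best


def _direct_pairs(calls, drug_map) -> set[tuple[str, str]]:
    tarsnp_genes = {c.gene_id for c in calls}
    return {
        (row.gene_id, row.drug_id)
        for row in drug_map.itertuples()
        if row.gene_id in tarsnp_genes
    }


def shortest_path_length(graph: nx.Graph, a: str, b: str) -> Optional[int]:
    """Unweighted shortest-path distance; None when disconnected."""
    if a not in graph or b not in graph:
        raise KeyError(f"node not in graph: {a if a not in graph else b}")
    try:
        return nx.shortest_path_length(graph, a, b)
    except nx.NetworkXNoPath:
        return None


def map_direct_targets(
    calls: list[TarSnpCall], drug_map: pd.DataFrame
) -> list[TargetAnnotation]:
    """Drug-target genes that themselves carry a tarSNP."""
    best = _best_call_per_gene(calls)
    annotations = []
    for row in drug_map.itertuples():
        call = best.get(row.gene_id)
        if call is None:
            continue
        annotations.append(
            TargetAnnotation(
                gene_id=row.gene_id,
                drug_id=row.drug_id,
                drug_name=row.drug_name,
                target_type=DIRECT,
                path_length=0,
                anchor_target=row.gene_id,
                response_direction=predict_response_direction(call.effect_class),
            )
        )
    annotations.sort(key=lambda a: (a.drug_id, a.gene_id))
    return annotations


def ppi_indirect_targets(
    calls: list[TarSnpCall], drug_map: pd.DataFrame, ppi: nx.Graph
) -> list[TargetAnnotation]:
    """tarSNP genes one PPI hop from a direct target (never re-annotating
    genes already direct for that drug)."""
    best = _best_call_per_gene(calls)
    direct = _direct_pairs(calls, drug_map)
    drug_names = {row.drug_id: row.drug_name for row in drug_map.itertuples()}
    directs_by_drug: dict[str, set] = {}
    for gene, drug in direct:
        directs_by_drug.setdefault(drug, set()).add(gene)

    annotations = []
    for drug_id in sorted(directs_by_drug):
        for gene_id, call in sorted(best.items()):
            if (gene_id, drug_id) in direct or gene_id not in ppi:
                continue
            neighbors = set(ppi.neighbors(gene_id)) & directs_by_drug[drug_id]
            if not neighbors:
                continue
            annotations.append(
                TargetAnnotation(
                    gene_id=gene_id,
                    drug_id=drug_id,
                    drug_name=drug_names[drug_id],
                    target_type=PPIN_INDIRECT,
                    path_length=1,
                    anchor_target=min(neighbors),
                    response_direction=predict_response_direction(call.effect_class),
                )
            )
    return annotations


def pathway_indirect_targets(
    calls: list[TarSnpCall],
    drug_map: pd.DataFrame,
    pathways: list[PathwayGraph],
) -> list[TargetAnnotation]:
    """tarSNP genes sharing a pathway with a direct target.

    Distance is the shortest path within the pathway's own edge set (None
    if disconnected). A gene co-member of several qualifying pathways is
    reported once per drug, at the minimum distance, ties broken by
    pathway_id.
    """
    best = _best_call_per_gene(calls)
    direct = _direct_pairs(calls, drug_map)
    drug_names = {row.drug_id: row.drug_name for row in drug_map.itertuples()}
    directs_by_drug: dict[str, set] = {}
    for gene, drug in direct:
        directs_by_drug.setdefault(drug, set()).add(gene)

    INF = float("inf")
    # (gene, drug) -> (distance, pathway_id, pathway_class, anchor)
    chosen: dict[tuple[str, str], tuple] = {}
    for pw in sorted(pathways, key=lambda p: p.pathway_id):
        for drug_id, directs in sorted(directs_by_drug.items()):
            anchors = sorted(directs & pw.members)
            if not anchors:
                continue
            for gene_id in sorted(pw.members):
                if gene_id not in best or (gene_id, drug_id) in direct:
                    continue
                dists = [
                    (d if (d := shortest_path_length(pw.graph, gene_id, t)) is not None else INF, t)
                    for t in anchors
                ]
                dist, anchor = min(dists)
                candidate = (dist, pw.pathway_id, pw.pathway_class, anchor)
                key = (gene_id, drug_id)
                if key not in chosen or candidate < chosen[key]:
                    chosen[key] = candidate
    annotations = []
    for (gene_id, drug_id), (dist, pid, pclass, anchor) in sorted(chosen.items()):
        annotations.append(
            TargetAnnotation(
                gene_id=gene_id,
                drug_id=drug_id,
                drug_name=drug_names[drug_id],
                target_type=PATHWAY_INDIRECT,
                path_length=None if dist == INF else int(dist),
                anchor_target=anchor,
                response_direction=predict_response_direction(best[gene_id].effect_class),
                pathway_id=pid,
                pathway_class=pclass,
            )
        )
    return annotations


def annotate_targets(
    calls: list[TarSnpCall],
    drug_map: pd.DataFrame,
    ppi: Optional[nx.Graph] = None,
    pathways: Optional[list[PathwayGraph]] = None,
) -> list[TargetAnnotation]:
    """Direct, then PPIN-indirect, then pathway-indirect annotations."""
    annotations = map_direct_targets(calls, drug_map)
    if ppi is not None:
        annotations += ppi_indirect_targets(calls, drug_map, ppi)
    if pathways is not None:
        annotations += pathway_indirect_targets(calls, drug_map, pathways)
    return annotations
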