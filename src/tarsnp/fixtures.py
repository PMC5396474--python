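"""Deterministic synthetic input bundles with planted ground truth.

Generates an internally consistent set of screening inputs — reference
FASTA, UTR BED, SNP VCF, mature miRNA FASTA, drug-target table, PPI edge
list and pathway tables — in which every tarSNP is planted by construction:

* planted sites are perfect 7-mer seed matches (miRNA positions 2-8) to a
  designated miRNA. A 7-mer is used because, under the default seed rules,
  a single substitution inside it (to a non-wobble base) abolishes every
  qualifying 6/7/8-mer seed, whereas a perfect 8-mer would survive one
  mismatch;
* complete gain/loss SNPs toggle a seed base between the Watson-Crick
  match and a non-pairing base; partial gain/loss SNPs toggle between the
  Watson-Crick match and a G:U wobble (site retained on both alleles, but
  weaker on the wobble allele);
* flanking sequence is rejection-sampled until the pipeline's own site
  finder confirms exactly the planted calls and nothing else, for every
  miRNA in the bundle;
* decoy SNPs sit in windows with no site for any miRNA; planted genes are
  wired to drugs directly, through a planted PPI edge, or through a
  planted pathway, so annotation counts are known exactly.

Everything derives from a single integer seed; the same seed yields
byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .classify import EffectClass, make_call
from .drug_network import predict_response_direction
from .reference_io import (
    AlleleWindow,
    MiRnaRecord,
    SnpRecord,
    UtrRecord,
    complement_base,
    make_allele_windows,
    reverse_complement,
)
from .target_scoring import EnergyModel, SeedRules, score_sequence

_BASES = "ACGT"
_RNA_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
_SEED_SNP_INDEX = 3  # in-site index of the planted SNP (pairs miRNA position 5)
_MAX_TRIES = 500

PLANTED_CLASSES = (
    EffectClass.COMPLETE_GAIN,
    EffectClass.COMPLETE_LOSS,
    EffectClass.PARTIAL_GAIN,
    EffectClass.PARTIAL_LOSS,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic bundle. Same seed -> byte-identical files."""

    seed: int = 0
    n_genes: int = 14
    utr_length: int = 160
    n_mirnas: int = 4
    n_snps: int = 10  # planted + decoy
    planted: dict = field(
        default_factory=lambda: {cls.value: 2 for cls in PLANTED_CLASSES}
    )
    n_drugs: int = 2
    ppi_edges: int = 10
    n_pathways: int = 3
    flank: int = 30

    @property
    def n_planted(self) -> int:
        return sum(self.planted.values())

    def validate(self) -> None:
        if self.n_planted > self.n_snps:
            raise ValueError(
                f"planted tarSNPs ({self.n_planted}) exceed n_snps ({self.n_snps})"
            )
        if self.n_genes < self.n_snps + 2:
            raise ValueError("need at least n_snps + 2 genes (fillers for pathways)")
        if self.utr_length < 80:
            raise ValueError("utr_length below 80 cannot hold a planted window")
        unknown = set(self.planted) - {cls.value for cls in PLANTED_CLASSES}
        if unknown:
            raise ValueError(f"unknown planted classes: {sorted(unknown)}")
        if self.n_mirnas < 1 or self.n_drugs < 1:
            raise ValueError("need at least one miRNA and one drug")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _random_mirnas(rng: np.random.Generator, n: int) -> list[MiRnaRecord]:
    """22-mers with distinct seed regions; seed positions 4-6 fixed to CGC.

    The planted SNP toggles the target base pairing position 5 between the
    Watson-Crick match (C) and the G:U wobble (T). The flanking C's pin the
    wobble between two G-C stacks, where the Turner table makes the wobble
    strictly weaker than the Watson-Crick pair — in other stack contexts a
    wobble can actually bind tighter, which would flip partial gain and
    loss plants.
    """
    mirnas: list[MiRnaRecord] = []
    seen_seeds: set[str] = set()
    while len(mirnas) < n:
        seq = "".join("ACGU"[i] for i in rng.integers(0, 4, size=22))
        seq = seq[:3] + "CGC" + seq[6:]
        if seq[1:8] in seen_seeds:
            continue
        seen_seeds.add(seq[1:8])
        mirnas.append(MiRnaRecord(mirna_id=f"mir-{len(mirnas) + 1:02d}", sequence=seq))
    return mirnas


def _perfect_site_dna(mirna: MiRnaRecord) -> str:
    """Sense-strand DNA of the perfect 7-mer target site (pairs positions
    2-8 antiparallel): site[k] is the WC partner of miRNA index 7-k."""
    return "".join(_RNA_WC[mirna.sequence[7 - k]] for k in range(7)).replace("U", "T")


def _nonpairing_base(rng: np.random.Generator, mirna_base: str) -> str:
    """A DNA base that neither WC- nor wobble-pairs the given miRNA base."""
    banned = {_RNA_WC[mirna_base].replace("U", "T")}
    if mirna_base == "G":
        banned.add("T")
    elif mirna_base == "U":
        banned.add("G")
    choices = sorted(set(_BASES) - banned)
    return choices[int(rng.integers(0, len(choices)))]


def _allele_bases(rng: np.random.Generator, effect_class: EffectClass) -> tuple[str, str]:
    """(wild, variant) sense bases at the planted seed position.

    The planted position pairs miRNA position 5 (forced to G): 'C' is the
    Watson-Crick match, 'T' the G:U wobble, 'A'/'G' abolish the pair.
    """
    broken = "AG"[int(rng.integers(0, 2))]
    return {
        EffectClass.COMPLETE_GAIN: (broken, "C"),
        EffectClass.COMPLETE_LOSS: ("C", broken),
        EffectClass.PARTIAL_GAIN: ("T", "C"),
        EffectClass.PARTIAL_LOSS: ("C", "T"),
    }[effect_class]


def _sense_windows(
    sense_seq: str, snp_index: int, wild: str, variant: str, snp_id: str,
    gene_id: str, flank: int,
) -> tuple[AlleleWindow, AlleleWindow]:
    """Windows as the pipeline will see them, built on the sense strand."""
    utr = UtrRecord(
        gene_id=gene_id, chrom="synthetic", start=0, end=len(sense_seq),
        strand="+", sequence=sense_seq,
    )
    snp = SnpRecord(
        snp_id=snp_id, chrom="synthetic", pos=snp_index + 1,
        ref_allele=wild, alt_allele=variant, gene_id=gene_id,
    )
    return make_allele_windows(snp, utr, flank=flank)


def _plant_gene(
    rng: np.random.Generator,
    spec: FixtureSpec,
    gene_id: str,
    snp_id: str,
    mirna: MiRnaRecord,
    others: list[MiRnaRecord],
    effect_class: EffectClass,
    model: EnergyModel,
    rules: SeedRules,
) -> tuple[str, int, str, str]:
    """Sense UTR with one planted tarSNP; verified by the site finder.

    Returns (sense sequence carrying the wild base, SNP sense index,
    wild base, variant base). Raises if no admissible sequence is found.
    """
    site = _perfect_site_dna(mirna)
    for _ in range(_MAX_TRIES):
        wild, variant = _allele_bases(rng, effect_class)
        seq = list(_random_dna(rng, spec.utr_length))
        p = int(rng.integers(31, spec.utr_length - 39))
        seq[p : p + 7] = site
        seq[p + _SEED_SNP_INDEX] = wild
        # block the 8-mer extension: the base 5' of the site pairs miRNA
        # position 9 in an 8-mer seed
        seq[p - 1] = _nonpairing_base(rng, mirna.sequence[8])
        sense = "".join(seq)
        snp_index = p + _SEED_SNP_INDEX

        w_wild, w_var = _sense_windows(
            sense, snp_index, wild, variant, snp_id, gene_id, spec.flank
        )
        s_wt = score_sequence(w_wild, mirna, model, rules)
        s_var = score_sequence(w_var, mirna, model, rules)
        call = make_call(
            snp_id, gene_id, mirna.mirna_id,
            None if s_wt is None else s_wt.score,
            None if s_var is None else s_var.score,
        )
        if call is None or call.effect_class is not effect_class:
            continue
        if any(
            score_sequence(w, other, model, rules) is not None
            for other in others
            for w in (w_wild, w_var)
        ):
            continue
        return sense, snp_index, wild, variant
    raise ValueError(
        f"could not plant a {effect_class.value} site for {gene_id}/{mirna.mirna_id}; "
        "spec appears infeasible"
    )


def _decoy_gene(
    rng: np.random.Generator,
    spec: FixtureSpec,
    gene_id: str,
    snp_id: str,
    mirnas: list[MiRnaRecord],
    model: EnergyModel,
    rules: SeedRules,
) -> tuple[str, int, str, str]:
    """Sense UTR with one SNP whose windows hold no site for any miRNA."""
    for _ in range(_MAX_TRIES):
        sense = _random_dna(rng, spec.utr_length)
        snp_index = int(rng.integers(31, spec.utr_length - 31))
        wild = sense[snp_index]
        variant = sorted(set(_BASES) - {wild})[int(rng.integers(0, 3))]
        w_wild, w_var = _sense_windows(
            sense, snp_index, wild, variant, snp_id, gene_id, spec.flank
        )
        if any(
            score_sequence(w, m, model, rules) is not None
            for m in mirnas
            for w in (w_wild, w_var)
        ):
            continue
        return sense, snp_index, wild, variant
    raise ValueError(f"could not place a siteless decoy SNP in {gene_id}")


def _build_genes(
    rng: np.random.Generator,
    spec: FixtureSpec,
    model: EnergyModel,
    rules: SeedRules,
):
    """miRNAs plus genes: planted tarSNPs, then decoy SNPs, then fillers."""
    mirnas = _random_mirnas(rng, spec.n_mirnas)
    planted_plan = [
        cls for cls in PLANTED_CLASSES for _ in range(spec.planted.get(cls.value, 0))
    ]
    genes = []  # (gene_id, strand, sense_seq)
    snps = []  # (snp_id, gene_id, snp_sense_index, wild, variant)
    truth_calls = []  # (snp_id, gene_id, mirna_id, class, direction)

    for i, cls in enumerate(planted_plan):
        gene_id = f"G{i + 1:02d}"
        snp_id = f"rsP{i + 1:03d}"
        strand = "+-"[i % 2]
        mirna = mirnas[i % len(mirnas)]
        others = [m for m in mirnas if m.mirna_id != mirna.mirna_id]
        sense, snp_index, wild, variant = _plant_gene(
            rng, spec, gene_id, snp_id, mirna, others, cls, model, rules
        )
        genes.append((gene_id, strand, sense))
        snps.append((snp_id, gene_id, snp_index, wild, variant))
        truth_calls.append(
            (snp_id, gene_id, mirna.mirna_id, cls.value, predict_response_direction(cls))
        )

    for j in range(spec.n_snps - spec.n_planted):
        idx = len(genes)
        gene_id = f"G{idx + 1:02d}"
        snp_id = f"rsD{j + 1:03d}"
        strand = "+-"[idx % 2]
        sense, snp_index, wild, variant = _decoy_gene(
            rng, spec, gene_id, snp_id, mirnas, model, rules
        )
        genes.append((gene_id, strand, sense))
        snps.append((snp_id, gene_id, snp_index, wild, variant))

    while len(genes) < spec.n_genes:
        idx = len(genes)
        genes.append((f"G{idx + 1:02d}", "+-"[idx % 2], _random_dna(rng, spec.utr_length)))
    return mirnas, genes, snps, truth_calls


def generate_bundle(spec: FixtureSpec, out_dir: str) -> dict[str, str]:
    """Write the full input bundle plus ground-truth tables to ``out_dir``.

    Returns a name -> path mapping for every file written, including a
    ready-to-run screen config.
    """
    spec.validate()
    model, rules = EnergyModel(), SeedRules()
    os.makedirs(out_dir, exist_ok=True)

    # Occasionally a drawn miRNA set is pathological (mutually similar
    # CG-rich seeds make incidental cross-matches near-certain); restart
    # the whole construction from a derived sub-seed when planting stalls.
    last_error: Exception | None = None
    for attempt in range(20):
        rng = np.random.default_rng([spec.seed, attempt])
        try:
            mirnas, genes, snps, truth_calls = _build_genes(rng, spec, model, rules)
            break
        except ValueError as exc:
            last_error = exc
    else:
        raise ValueError(f"fixture generation failed for seed {spec.seed}: {last_error}")

    # --- contig assembly ---------------------------------------------------
    spacer = 20
    contig_parts, utr_start, bed_rows = [], {}, []
    cursor = 0
    for gene_id, strand, sense in genes:
        contig_parts.append(_random_dna(rng, spacer))
        cursor += spacer
        utr_start[gene_id] = cursor
        segment = sense if strand == "+" else reverse_complement(sense)
        contig_parts.append(segment)
        bed_rows.append(("chr1", cursor, cursor + len(sense), gene_id, 0, strand))
        cursor += len(sense)
    contig_parts.append(_random_dna(rng, spacer))
    cursor += spacer
    contig = "".join(contig_parts)

    strand_of = {g: s for g, s, _ in genes}
    length_of = {g: len(seq) for g, _, seq in genes}
    vcf_rows = []
    for snp_id, gene_id, snp_index, wild, variant in snps:
        start = utr_start[gene_id]
        if strand_of[gene_id] == "+":
            pos0 = start + snp_index
            ref, alt = wild, variant
        else:
            pos0 = start + length_of[gene_id] - 1 - snp_index
            ref, alt = complement_base(wild), complement_base(variant)
        vcf_rows.append((pos0 + 1, snp_id, ref, alt))
    vcf_rows.sort()

    # --- drugs and networks ------------------------------------------------
    planted_genes = [row[1] for row in truth_calls]
    class_of = {row[1]: row[3] for row in truth_calls}
    roles = ["direct", "ppin_indirect", "pathway_indirect"]
    role_of = {g: roles[i % 3] for i, g in enumerate(planted_genes)}
    directs = [g for g in planted_genes if role_of[g] == "direct"]
    ppin_genes = [g for g in planted_genes if role_of[g] == "ppin_indirect"]
    pathway_genes = [g for g in planted_genes if role_of[g] == "pathway_indirect"]
    if not directs and (ppin_genes or pathway_genes):
        raise ValueError("indirect plants require at least one direct target")
    fillers = [g for g, _, _ in genes if g not in set(planted_genes)]

    drug_rows = [
        (f"D{(i % spec.n_drugs) + 1:02d}", f"drug-{(i % spec.n_drugs) + 1:02d}", g)
        for i, g in enumerate(directs)
    ]
    drug_of = {g: d for d, _, g in drug_rows}

    truth_annotations = [
        (g, drug_of[g], "direct", 0, predict_response_direction(EffectClass(class_of[g])))
        for g in directs
    ]

    ppi_rows = []
    for i, g in enumerate(ppin_genes):
        anchor = directs[i % len(directs)]
        ppi_rows.append((g, anchor))
        truth_annotations.append(
            (g, drug_of[anchor], "ppin_indirect", 1,
             predict_response_direction(EffectClass(class_of[g])))
        )
    # decoy edges among fillers (and filler-direct), never touching tarSNP
    # genes on both ends, so they create no extra annotations
    decoy_pool = fillers + directs
    tries = 0
    while len(ppi_rows) < spec.ppi_edges and fillers and tries < 1000:
        tries += 1
        a = fillers[int(rng.integers(0, len(fillers)))]
        b = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
        if a != b and (a, b) not in ppi_rows and (b, a) not in ppi_rows:
            ppi_rows.append((a, b))

    pathway_member_rows, pathway_edge_rows = [], []
    for i, g in enumerate(pathway_genes):
        pid = f"PW{i + 1:02d}"
        pclass = ("metabolic", "nonmetabolic")[i % 2]
        anchor = directs[i % len(directs)]
        bridge = fillers[i % len(fillers)]
        for member in (anchor, bridge, g):
            pathway_member_rows.append((pid, pclass, member))
        if i % 2 == 0:  # direct edge: distance 1
            pathway_edge_rows.append((pid, anchor, g))
            pathway_edge_rows.append((pid, anchor, bridge))
            dist = 1
        else:  # chain through the bridge: distance 2
            pathway_edge_rows.append((pid, anchor, bridge))
            pathway_edge_rows.append((pid, bridge, g))
            dist = 2
        truth_annotations.append(
            (g, drug_of[anchor], "pathway_indirect", dist,
             predict_response_direction(EffectClass(class_of[g])))
        )
    for k in range(len(pathway_genes), spec.n_pathways):  # decoy pathways
        pid = f"PW{k + 1:02d}"
        members = [fillers[(k + j) % len(fillers)] for j in range(3)]
        for member in sorted(set(members)):
            pathway_member_rows.append((pid, "nonmetabolic", member))

    # --- serialization -----------------------------------------------------
    paths = {name: os.path.join(out_dir, fname) for name, fname in [
        ("fasta", "reference.fa"), ("bed", "utrs.bed"), ("vcf", "snps.vcf"),
        ("mirna_fasta", "mirnas.fa"), ("drug_map", "drug_targets.tsv"),
        ("ppi", "ppi_edges.tsv"), ("pathway_members", "pathway_members.tsv"),
        ("pathway_edges", "pathway_edges.tsv"),
        ("truth_calls", "truth_calls.tsv"),
        ("truth_annotations", "truth_annotations.tsv"),
        ("config", "config.yaml"),
    ]}

    with open(paths["fasta"], "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(contig), 60):
            fh.write(contig[i : i + 60] + "\n")

    with open(paths["bed"], "w") as fh:
        for row in bed_rows:
            fh.write("\t".join(map(str, row)) + "\n")

    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={len(contig)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, snp_id, ref, alt in vcf_rows:
            fh.write(f"chr1\t{pos}\t{snp_id}\t{ref}\t{alt}\t.\tPASS\t.\n")

    with open(paths["mirna_fasta"], "w") as fh:
        for m in mirnas:
            fh.write(f">{m.mirna_id}\n{m.sequence}\n")

    def _write_tsv(path, header, rows):
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")

    _write_tsv(paths["drug_map"], ["drug_id", "drug_name", "gene_id"], drug_rows)
    _write_tsv(paths["ppi"], ["gene_a", "gene_b"], ppi_rows)
    _write_tsv(
        paths["pathway_members"], ["pathway_id", "pathway_class", "gene_id"],
        pathway_member_rows,
    )
    _write_tsv(
        paths["pathway_edges"], ["pathway_id", "gene_a", "gene_b"], pathway_edge_rows
    )
    _write_tsv(
        paths["truth_calls"],
        ["snp_id", "gene_id", "mirna_id", "effect_class", "response_direction"],
        truth_calls,
    )
    _write_tsv(
        paths["truth_annotations"],
        ["gene_id", "drug_id", "target_type", "path_length", "response_direction"],
        truth_annotations,
    )

    config = {
        "fasta": "reference.fa",
        "bed": "utrs.bed",
        "vcf": "snps.vcf",
        "mirna_fasta": "mirnas.fa",
        "drug_map": "drug_targets.tsv",
        "ppi": "ppi_edges.tsv",
        "pathway_members": "pathway_members.tsv",
        "pathway_edges": "pathway_edges.tsv",
        "out_dir": "results",
        "flank": spec.flank,
        "accessibility": False,
        "min_abs_diff": 0.0,
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    return paths


def load_fixture_spec(path: str) -> FixtureSpec:
    """Read a FixtureSpec from a YAML file (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return FixtureSpec(**data)
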