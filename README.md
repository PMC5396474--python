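# tarsnp

Screen 3′ UTR SNPs for microRNA target sites that are created, destroyed,
strengthened or weakened by the variant allele (*tarSNPs*), and propagate the
predicted regulatory change to drug targets — directly, through the
protein–protein interaction network, and through shared pathways — to
predict the direction of a drug-response alteration.

## Who this is for

Pharmacogenomics and regulatory-genomics analysts who have a set of 3′ UTR
variants (VCF), UTR annotations (BED + reference FASTA), mature miRNA
sequences (FASTA), and drug-target / PPI / pathway tables (TSV), and want a
reproducible desk-scale pipeline from raw variants to per-drug
sensitivity/resistance calls.

## The model

For each SNP inside an annotated 3′ UTR, the pipeline extracts the 30 nt of
flanking sequence on each side (a ≤ 61 nt window, truncated at UTR
boundaries, on the transcript sense strand) for the wild-type and variant
alleles. Each window is scanned for candidate seed sites (miRNA positions
2–8, with configurable G:U-wobble and mismatch allowances) and each site is
scored with a Turner nearest-neighbor free energy:

    score = ΔG_duplex + ΔG_open

where ΔG_duplex is the seed-duplex hybridization energy (kcal/mol) and
ΔG_open is the optional cost of unpairing the site out of the window's own
secondary structure (off by default). The best per-allele scores, T_wt and
T_var (absent when no site qualifies), give the binding change

    ΔΔG = diff = T_wt − T_var        (absent → 0)

A positive diff means the variant allele binds the miRNA more strongly.
Calls are classified as **complete gain** (site created), **complete loss**
(site destroyed), **partial gain** / **partial loss** (both alleles have
sites, variant more / less stable); diff = 0 is not a tarSNP. For
prioritization, diff is normalized by the larger score magnitude
(diff / max(|T_wt|, |T_var|)), which pins complete gains/losses at ±1.

A tarSNP-bearing gene that is itself a drug target is a **direct** target;
one adjacent to a direct target in the PPI graph is **PPIN-indirect**
(distance 1); one sharing a pathway with a direct target is
**pathway-indirect**, with the shortest-path distance inside the pathway's
edge set. Gain classes predict **drug sensitivity** (more repression → less
target protein); loss classes predict **drug resistance**.

## Worked example

Generate a fully synthetic, deterministic input bundle with two planted
SNPs per effect class, then run the screen:

```bash
tarsnp fixtures --seed 1 --out demo
tarsnp screen --config demo/config.yaml
```

`demo/results/tarsnps.tsv` (prioritized by |normalized ΔΔG|):

```text
snp_id  gene_id  mirna_id  wild_energy  mutation_energy  ddG    effect_class   norm_ddG
rsP004  G04      mir-04    -11.8        None             -11.8  complete_loss  -1
rsP002  G02      mir-02    None         -10.6            10.6   complete_gain  1
rsP003  G03      mir-03    -10.2        None             -10.2  complete_loss  -1
rsP001  G01      mir-01    None         -8.8             8.8    complete_gain  1
rsP005  G05      mir-01    -6.9         -8.8             1.9    partial_gain   0.215909
rsP007  G07      mir-03    -10.2        -8.3             -1.9   partial_loss   -0.186275
rsP006  G06      mir-02    -8.7         -10.6            1.9    partial_gain   0.179245
rsP008  G08      mir-04    -11.8        -9.9             -1.9   partial_loss   -0.161017
```

Reading the first row: on the wild-type allele, mir-04 binds G04's UTR at
−11.8 kcal/mol; the variant allele has no qualifying site (`None`), so the
site is destroyed (ΔΔG = −11.8, complete loss) and the normalized change is
−1. `demo/results/drug_annotations.tsv` then maps each call onto drugs, e.g.

```text
drug  snp_id  gene_id  ...  ddG    effect_class   target_type      anchor_target  path_length  pathway_id  response_direction
D01   rsP001  G01      ...  8.8    complete_gain  direct           G01            0            None        sensitivity
D01   rsP002  G02      ...  10.6   complete_gain  ppin_indirect    G01            1            None        sensitivity
D02   rsP006  G06      ...  1.9    partial_gain   pathway_indirect G04            2            PW02        sensitivity
```

G02 is not a drug target itself, but interacts with the direct target G01,
so the gained miR-02 site on G02 is predicted to increase sensitivity to
drug D01 one hop away.

Two further subcommands work on tables instead of sequence:
`tarsnp classify --scores scores.tsv --out calls.tsv` runs the
diff/classification stage on a precomputed per-allele score table
(columns `snp_id, mirna_id, allele, score`; empty score = no site), and
`tarsnp annotate` re-runs only the drug/network stage on existing calls.

## Layout

- `src/tarsnp/reference_io.py` — FASTA/BED/VCF/miRNA readers, strand
  resolution, allele windows
- `src/tarsnp/target_scoring.py` — seed-site discovery, nearest-neighbor
  energies, accessibility, pluggable score providers
- `src/tarsnp/classify.py` — ΔΔG, four-class gain/loss, normalization,
  ranking
- `src/tarsnp/drug_network.py` — direct / PPIN-indirect / pathway-indirect
  targets, response direction
- `src/tarsnp/fixtures.py` — deterministic synthetic bundles with planted
  ground truth
- `src/tarsnp/report.py`, `src/tarsnp/cli.py` — orchestration and the
  `tarsnp` command

See `docs/methods.md` for the modeling choices and their limitations.
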