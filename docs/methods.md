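# Methods

This note records the model, the defaults, and the places where a design
choice was genuinely open — and what the tests do and do not demonstrate.

## Windows and coordinates

BED intervals are 0-based half-open; VCF positions are 1-based. The single
conversion lives in `reference_io.vcf_pos_to_zero_based`. Windows are the
intersection of [SNP − 30, SNP + 30] with the UTR, so a SNP near a UTR end
gets a shorter window; windows are never padded into CDS or intergenic
sequence. All windows are expressed on the transcript sense strand: for
minus-strand genes the UTR sequence is reverse-complemented at load time and
the VCF alleles are complemented during window construction. Only biallelic
SNVs are evaluated; multi-allelic records are split into one candidate per
alternate allele, indels are dropped, and a SNP covered by overlapping UTRs
is evaluated once per gene. The flank length (default 30 nt) is a config
key.

## Seed rules

Candidate sites anchor at miRNA position 2 and span 6, 7 or 8 bases.
Allowances per seed length: 6-mers must be perfect; 7-mers tolerate one G:U
wobble; 8-mers tolerate one wobble or one mismatch; never more than one
imperfection in total. All of this is configurable through `SeedRules`.
Site existence is *not* thresholded on the score's sign — a qualifying seed
with a positive (unfavorable) free energy still counts as a site, so a
variant can "gain" a weak site.

## Energy model

Hybridization uses the published Turner 2004 RNA/RNA nearest-neighbor stack
free energies at 37 °C (kcal/mol), embedded as constants, with duplex
initiation +4.10 and a +0.50 penalty per terminal A-U or G:U pair. DNA
windows are transcribed to RNA before pairing. The scored duplex is the
seed region only (miRNA positions 2..seed_len+1 against the site);
3′-supplementary pairing is not modeled. Unpaired duplex positions cost a
flat +1.0 loop penalty each — charged at every unpaired position, not only
interior ones, which makes the model provably monotone: converting any true
mismatch to a Watson-Crick pair can never raise the energy. Note the
monotonicity guarantee is about mismatches, not wobbles: under the Turner
stacks a G:U wobble can bind *tighter* than the A-U pair it would become
(e.g. 5′AU/3′UG stacks at −1.40 vs 5′AU/3′UA at −1.10), so
"wobble → Watson-Crick" is not uniformly stabilizing.

Per (window, miRNA) the reported score is the minimum over all qualifying
sites; ties break to the smallest window offset, then the shortest seed.
The scorer is a pure function — identical inputs give bit-identical output.

### Accessibility (ΔG_open)

Optionally (off by default) each site pays the cost of being unpaired in
the window's own secondary structure: ΔG_open = E(window with the site
region forced single-stranded) − E(window), clamped at ≥ 0, where E is the
minimum stacking free energy over nested structures (helix stacks from the
same table, hairpin loops ≥ 3 nt, no loop entropies). Ignoring loop
entropies underestimates both terms; only their difference is used. At the
default desk scale accessibility is disabled because the 61 nt window is
too short to represent the mRNA's real structural context; enabling it is a
single config flag.

### Pluggable scores

Any external per-allele score table (TSV: `snp_id, mirna_id, allele,
score`, empty = no site) can replace the engine, so scores from a
third-party target predictor can be dropped in; the downstream
diff/classification/annotation path is identical either way, and the test
suite verifies that feeding the engine's own emitted table back in
reproduces the reports byte for byte.

## Diff, classes, normalization

diff = T_wt − T_var with absent scores entering as 0; this makes the diff
of a complete gain/loss equal the signed magnitude of the surviving score,
matching how such rows are conventionally reported. Classes follow the
truth table: wild absent → complete gain; variant absent → complete loss;
both present → partial gain/loss by the sign of diff; diff = 0 → not a
tarSNP. The normalizer divides by max(|T_wt|, |T_var|) (absent → 0; 0/0
defined as 0). A literal max over two negative energies would divide by the
*weaker* score and explode near zero; magnitude normalization bounds
|norm| ≤ 2 and pins complete gains/losses at ±1, which is what a
prioritization statistic needs. Ranking is by descending |norm diff|, ties
by |diff| then ids — fully deterministic. A configurable minimum |diff|
(default 0) filters marginal calls.

## Drug and network propagation

Direct targets are drug-map genes that themselves carry a tarSNP.
PPIN-indirect is strictly one hop (first neighbors of a direct target),
never transitive closure, and a gene already direct for a drug is not
re-annotated for it. Pathway-indirect genes share a pathway with a direct
target; distance is the unweighted shortest path within that pathway's own
edge set (absent when disconnected), computed per pathway rather than on a
pathway-union graph. When only membership tables exist, a config flag
treats co-membership as a clique (all distances 1). A gene in several
qualifying pathways is reported once per drug at the minimum distance, ties
broken by pathway id. Response direction applies the target-protein logic
uniformly: gain classes → sensitivity, loss classes → resistance. Indirect
neighbors could in principle regulate the target in either direction; that
second-order sign is not modeled, and the annotation reports the tarSNP
gene's own regulation change.

## Synthetic bundles and what they show

The fixture generator plants tarSNPs with known classes: a perfect 7-mer
seed toggled by a single base. A 7-mer is used deliberately — an 8-mer
survives one mismatch under the default rules, so no single-base change
could abolish it, while a 7-mer (which tolerates only a wobble) is
destroyed by any non-wobble substitution; the adjacent base is chosen so no
8-mer forms across the site. Partial gains/losses toggle the site base
pairing miRNA position 5 between Watson-Crick and G:U; generated miRNAs fix
seed positions 4–6 to CGC so the wobble sits between two G-C stacks, a
context where it is strictly the weaker pair (see above for why context
matters). Flanks are rejection-sampled until the pipeline's own site finder
confirms exactly the planted calls and nothing else for every miRNA in the
bundle, and decoy SNP windows are siteless by the same check; occasionally
a drawn miRNA set makes incidental matches near-certain, in which case the
construction restarts deterministically from a derived sub-seed. Genes
alternate strands so minus-strand bookkeeping is exercised end to end, and
planted genes are wired to drugs as direct, PPI-adjacent, or co-pathway
members with known distances.

Defaults: 14 genes with 160 nt UTRs, 4 miRNAs (22 nt), 10 SNPs (2 planted
per effect class + 2 decoys), 2 drugs, 10 PPI edges, 3 pathways — small
enough that every stage is exhaustively checkable, large enough that every
code path (both strands, both indirect routes, decoys) runs.

What passing on these bundles shows: the coordinate/strand bookkeeping,
site discovery, energy ordering, classification and network propagation
are internally correct. What it does not show: performance on real 3′ UTRs
(realistic base composition, RNA structure, allele frequencies, LD), nor
agreement with any particular third-party scorer's numeric output — real
per-allele scores should be supplied through the score-table interface when
exact published site scores matter.

## Numerical and tie-break choices

- Absent vs 0: an absent score means "no qualifying site", distinct from a
  site scoring 0.0; a pair absent on both alleles is dropped before diff.
- Equal-score sites tie-break to the smallest window offset, then seed
  length; ranking ties break by |diff| then (snp, miRNA, gene) ids.
- Report floats are printed at up to 6 significant digits; absent values
  print as `None`.
- Reference mismatches (VCF REF disagreeing with the FASTA base) are
  warnings, not errors, and the REF allele as stated is used.

## Known limitations

No conservation filtering, no CDS/5′ UTR sites, no 3′-supplementary
pairing, no patient-level aggregation beyond ranking, no statistical
significance on diffs, and network propagation treats all interactions as
undirected and unweighted.
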