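"""Seed-site discovery and free-energy scoring of miRNA:target duplexes.

The scorer is accessibility-aware in the style of seed-plus-energy target
predictors: candidate sites are seed matches (miRNA positions 2..8, with
configurable G:U wobble and mismatch allowances), each site is scored as

    score = dG_duplex + dG_open

where ``dG_duplex`` is a gap-free antiparallel nearest-neighbor sum over the
seed duplex (miRNA positions 2..seed_len+1 against the site; supplementary
3' pairing is not modeled), and ``dG_open`` (off by default)
is the cost of unpairing the site region out of the window's own secondary
structure. The best (most negative) site score per (window, miRNA) is
reported; windows with no qualifying seed site score as absent.

Energies are Turner 2004 RNA/RNA nearest-neighbor stack free energies at
37 C (kcal/mol), embedded below, with duplex initiation and terminal AU/GU
penalties.

A precomputed score table (snp_id, mirna_id, allele, score) can stand in
for the engine via :class:`TableScoreProvider`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Optional, Protocol

from .reference_io import AlleleWindow, MiRnaRecord

# ---------------------------------------------------------------------------
# Embedded nearest-neighbor parameters (Turner 2004, kcal/mol at 37 C)
# ---------------------------------------------------------------------------

_PAIRS = [("C", "G"), ("G", "C"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")]

# Stack free energies: row = outer pair (5' top base, 3' bottom base),
# column = inner pair read from the opposite strand, the convention of the
# published tables. Rebuilt below into a flat dict keyed by
# (outer_pair, inner_pair) with both pairs read top-strand first.
_STACK_MATRIX = [
    # CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]

DUPLEX_INIT = 4.10  # duplex initiation penalty
AU_END_PENALTY = 0.50  # per terminal AU or GU pair
MISMATCH_PENALTY = 1.00  # per internal unpaired duplex position

WC_PAIRS = frozenset([("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")])
GU_PAIRS = frozenset([("G", "U"), ("U", "G")])
_WEAK_PAIRS = frozenset([("A", "U"), ("U", "A")]) | GU_PAIRS


def _build_stack_table() -> dict[tuple[tuple[str, str], tuple[str, str]], float]:
    idx = {p: i for i, p in enumerate(_PAIRS)}
    table = {}
    for outer in _PAIRS:
        for inner in _PAIRS:
            # column label of the published matrix is the inner pair as seen
            # from the other strand, i.e. (bottom, top)
            table[(outer, inner)] = _STACK_MATRIX[idx[outer]][idx[(inner[1], inner[0])]]
    return table


STACK_TABLE = _build_stack_table()


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor energy parameters and scoring switches."""

    nn_stack_table: dict = field(default_factory=lambda: dict(STACK_TABLE))
    init_penalty: float = DUPLEX_INIT
    au_end_penalty: float = AU_END_PENALTY
    mismatch_penalty: float = MISMATCH_PENALTY
    gu_allowed: bool = True
    accessibility_enabled: bool = False


@dataclass(frozen=True)
class SeedRules:
    """Which seed matches qualify as candidate sites.

    Seeds anchor at miRNA position 2 and span ``seed_len`` bases
    (positions 2..seed_len+1). Per seed length, at most ``gu_allowance``
    G:U wobbles and ``mismatch_allowance`` mismatches are tolerated, with
    at most ``max_imperfections`` imperfections in total.
    """

    seed_lengths: tuple[int, ...] = (6, 7, 8)
    gu_allowance: dict = field(default_factory=lambda: {7: 1, 8: 1})
    mismatch_allowance: dict = field(default_factory=lambda: {8: 1})
    max_imperfections: int = 1

    def qualifies(self, seed_len: int, gu: int, mismatch: int) -> bool:
        return (
            gu <= self.gu_allowance.get(seed_len, 0)
            and mismatch <= self.mismatch_allowance.get(seed_len, 0)
            and gu + mismatch <= self.max_imperfections
        )


@dataclass(frozen=True)
class SeedSite:
    """One candidate seed match within a window.

    ``window_start`` is the 0-based window index of the site's 5'-most
    base, the one pairing the highest seed position of the miRNA.
    """

    window_start: int
    seed_len: int
    gu_count: int
    mismatch_count: int


@dataclass(frozen=True)
class SiteScore:
    """Free-energy score of the best site of one miRNA on one window."""

    dG_duplex: float
    dG_open: float
    score: float
    site: Optional[SeedSite] = None


def transcribe(dna: str) -> str:
    """DNA window (sense strand) -> RNA, for pairing against the miRNA."""
    return dna.upper().replace("T", "U")


def _window_seq(window) -> str:
    seq = window.sequence if isinstance(window, AlleleWindow) else window
    return transcribe(seq)


def _is_pair(a: str, b: str, gu_allowed: bool = True) -> bool:
    return (a, b) in WC_PAIRS or (gu_allowed and (a, b) in GU_PAIRS)


def find_seed_sites(
    window, mirna: MiRnaRecord, rules: SeedRules | None = None
) -> list[SeedSite]:
    """Enumerate all qualifying seed sites of ``mirna`` on ``window``.

    Exhaustive over window offsets and seed lengths; deterministic order
    (ascending window_start, then seed length). The target site pairs the
    miRNA seed antiparallel: the site's 3'-most base pairs miRNA
    position 2.
    """
    rules = rules or SeedRules()
    w = _window_seq(window)
    m = mirna.sequence
    sites: list[SeedSite] = []
    for s in sorted(rules.seed_lengths):
        if len(m) < s + 1 or len(w) < s:
            continue
        for ws in range(len(w) - s + 1):
            gu = mm = 0
            for k in range(s):
                mb = m[s - k]  # miRNA positions s+1 .. 2 along the site
                tb = w[ws + k]
                if (mb, tb) in WC_PAIRS:
                    continue
                if (mb, tb) in GU_PAIRS:
                    gu += 1
                else:
                    mm += 1
            if rules.qualifies(s, gu, mm):
                sites.append(
                    SeedSite(window_start=ws, seed_len=s, gu_count=gu, mismatch_count=mm)
                )
    sites.sort(key=lambda site: (site.window_start, site.seed_len))
    return sites


def duplex_energy(mirna_sub: str, target_sub: str, model: EnergyModel | None = None) -> float:
    """Nearest-neighbor free energy of a gap-free antiparallel duplex.

    Both strands are given 5'->3'; position ``i`` of the miRNA strand pairs
    position ``L-1-i`` of the target strand. The energy is the initiation
    penalty plus stack terms over consecutive paired positions, terminal
    AU/GU penalties on the outermost pairs, and a fixed loop penalty for
    every unpaired position. Charging all unpaired positions (not just
    interior ones) keeps the model monotone: turning any mismatch into a
    Watson-Crick pair can never raise the energy.
    """
    model = model or EnergyModel()
    if len(mirna_sub) != len(target_sub):
        raise ValueError(
            f"duplex strands differ in length: {len(mirna_sub)} vs {len(target_sub)}"
        )
    L = len(mirna_sub)
    pairs = [(mirna_sub[i], target_sub[L - 1 - i]) for i in range(L)]
    valid = [_is_pair(a, b, model.gu_allowed) for a, b in pairs]

    energy = model.init_penalty + model.mismatch_penalty * (L - sum(valid))
    if not any(valid):
        return energy

    for i in range(L - 1):
        if valid[i] and valid[i + 1]:
            energy += model.nn_stack_table[(pairs[i], pairs[i + 1])]

    first = valid.index(True)
    last = L - 1 - valid[::-1].index(True)
    for i in {first, last}:
        if pairs[i] in _WEAK_PAIRS:
            energy += model.au_end_penalty
    return energy


# ---------------------------------------------------------------------------
# Site accessibility (dG_open)
# ---------------------------------------------------------------------------


def _fold_min_energy(seq: str, blocked: frozenset[int], model: EnergyModel) -> float:
    """Minimum stacking free energy of any secondary structure of ``seq``.

    A stripped-down fold: energy accrues only from helix stacks (the same
    nearest-neighbor table as the duplex), hairpin loops need >= 3 unpaired
    bases, and positions in ``blocked`` may not pair. Loop entropies are
    ignored, so this underestimates structure free energies uniformly; it
    is used only for the constrained-minus-unconstrained difference.
    """
    n = len(seq)
    NEG = float("inf")

    def pairable(i: int, j: int) -> bool:
        if i in blocked or j in blocked or j - i - 1 < 3:
            return False
        return _is_pair(seq[i], seq[j], model.gu_allowed)

    # V[i][j]: min energy of s[i..j] given (i,j) paired; W[i][j]: min overall
    V = [[NEG] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]
    for span in range(4, n):
        for i in range(n - span):
            j = i + span
            if pairable(i, j):
                best = W[i + 1][j - 1]
                if pairable(i + 1, j - 1) and V[i + 1][j - 1] < NEG:
                    stacked = (
                        model.nn_stack_table[((seq[i], seq[j]), (seq[i + 1], seq[j - 1]))]
                        + V[i + 1][j - 1]
                    )
                    best = min(best, stacked)
                V[i][j] = best
            w = min(W[i + 1][j], W[i][j - 1])
            if V[i][j] < NEG:
                w = min(w, V[i][j])
            for k in range(i + 1, j):
                w = min(w, W[i][k] + W[k + 1][j])
            W[i][j] = w
    return W[0][n - 1] if n else 0.0


def accessibility_energy(window, site: SeedSite, model: EnergyModel | None = None) -> float:
    """Cost (>= 0) of unpairing the site region out of the window structure.

    Zero whenever accessibility is disabled in the model.
    """
    model = model or EnergyModel()
    if not model.accessibility_enabled:
        return 0.0
    w = _window_seq(window)
    site_region = frozenset(range(site.window_start, site.window_start + site.seed_len))
    e_free = _fold_min_energy(w, frozenset(), model)
    e_open = _fold_min_energy(w, site_region, model)
    return max(0.0, e_open - e_free)


# ---------------------------------------------------------------------------
# Per-window scoring
# ---------------------------------------------------------------------------


def _site_duplex(w_rna: str, mirna: MiRnaRecord, site: SeedSite) -> tuple[str, str]:
    """The seed duplex: miRNA positions 2..seed_len+1 against the site."""
    mirna_sub = mirna.sequence[1 : site.seed_len + 1]
    target_sub = w_rna[site.window_start : site.window_start + site.seed_len]
    return mirna_sub, target_sub


def score_site(
    window, mirna: MiRnaRecord, site: SeedSite, model: EnergyModel | None = None
) -> SiteScore:
    model = model or EnergyModel()
    w_rna = _window_seq(window)
    mirna_sub, target_sub = _site_duplex(w_rna, mirna, site)
    dg_duplex = duplex_energy(mirna_sub, target_sub, model)
    dg_open = accessibility_energy(window, site, model)
    return SiteScore(
        dG_duplex=dg_duplex, dG_open=dg_open, score=dg_duplex + dg_open, site=site
    )


def score_sequence(
    window,
    mirna: MiRnaRecord,
    model: EnergyModel | None = None,
    rules: SeedRules | None = None,
) -> Optional[SiteScore]:
    """Best (most negative) site score of ``mirna`` on ``window``.

    Returns None iff no qualifying seed site exists; site existence is not
    thresholded on the score's sign. Equal-score ties break to the
    smallest window_start, then shortest seed.
    """
    sites = find_seed_sites(window, mirna, rules)
    if not sites:
        return None
    scored = [score_site(window, mirna, s, model) for s in sites]
    return min(scored, key=lambda sc: (sc.score, sc.site.window_start, sc.site.seed_len))


# ---------------------------------------------------------------------------
# Pluggable score providers
# ---------------------------------------------------------------------------


class ScoreProvider(Protocol):
    """Anything that yields a per-allele binding score (None = no site)."""

    def score(self, snp_id: str, mirna_id: str, allele: str, window, mirna) -> Optional[float]:
        ...


@dataclass(frozen=True)
class EngineScoreProvider:
    """Scores windows with the in-package seed + energy engine."""

    model: EnergyModel = field(default_factory=EnergyModel)
    rules: SeedRules = field(default_factory=SeedRules)

    def score(self, snp_id, mirna_id, allele, window, mirna):
        result = score_sequence(window, mirna, self.model, self.rules)
        return None if result is None else result.score


class TableScoreProvider:
    """Serves scores from a precomputed table instead of the engine.

    The table is a TSV with columns snp_id, mirna_id, allele (wild|variant)
    and score; an empty score field means no site. Pairs absent from the
    table are treated as having no site.
    """

    def __init__(self, table: dict[tuple[str, str, str], Optional[float]]):
        self._table = dict(table)

    @classmethod
    def from_tsv(cls, path: str) -> "TableScoreProvider":
        table: dict[tuple[str, str, str], Optional[float]] = {}
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                raw = (row.get("score") or "").strip()
                value = None if raw in ("", "None", "NA") else float(raw)
                table[(row["snp_id"], row["mirna_id"], row["allele"])] = value
        return cls(table)

    def score(self, snp_id, mirna_id, allele, window=None, mirna=None):
        return self._table.get((snp_id, mirna_id, allele))
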