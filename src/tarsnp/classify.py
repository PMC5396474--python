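"""Allele-difference statistics and gain/loss classification of tarSNPs.

For each (SNP, miRNA, gene) triple with per-allele binding scores T_wt and
T_var (kcal/mol; absent when the allele carries no predicted site), the
binding change is

    diff = T_wt - T_var        (absent scores enter as 0)

so a positive diff means the variant allele binds more strongly (gain of
miRNA regulation) and a negative diff means weaker binding (loss). Calls
fall into four effect classes: *complete gain* (site created by the variant
allele), *complete loss* (site destroyed), *partial gain* (both alleles
have sites, variant more stable) and *partial loss* (variant less stable).
SNPs with diff == 0 are not tarSNPs.

For prioritization across multiple tarSNPs, diff is normalized by the
larger of the two score magnitudes, bounding |norm_diff| <= 2 and pinning
complete gain/loss at +1/-1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional


class EffectClass(str, enum.Enum):
    COMPLETE_GAIN = "complete_gain"
    COMPLETE_LOSS = "complete_loss"
    PARTIAL_GAIN = "partial_gain"
    PARTIAL_LOSS = "partial_loss"
    NO_EFFECT = "no_effect"

    def __str__(self) -> str:  # plain value in reports
        return self.value


GAIN_CLASSES = frozenset({EffectClass.COMPLETE_GAIN, EffectClass.PARTIAL_GAIN})
LOSS_CLASSES = frozenset({EffectClass.COMPLETE_LOSS, EffectClass.PARTIAL_LOSS})


@dataclass(frozen=True)
class TarSnpCall:
    """Paired per-allele scores and their classified difference."""

    snp_id: str
    gene_id: str
    mirna_id: str
    t_wt: Optional[float]
    t_var: Optional[float]
    diff: float
    norm_diff: float
    effect_class: EffectClass


def compute_diff(t_wt: Optional[float], t_var: Optional[float]) -> float:
    """diff = T_wt - T_var, with an absent score entering as 0.

    The zero substitution makes diff equal the signed magnitude of the
    surviving score for complete gains/losses. Pairs where both scores are
    absent carry no information and must be filtered before this point.
    """
    if t_wt is None and t_var is None:
        raise ValueError("both allele scores absent; pair should have been filtered")
    return (t_wt if t_wt is not None else 0.0) - (t_var if t_var is not None else 0.0)


def classify_effect(
    t_wt: Optional[float], t_var: Optional[float], diff: float
) -> EffectClass:
    """Assign the four-class gain/loss label.

    Site created by the variant allele -> complete gain; site destroyed ->
    complete loss; both sites present -> partial gain (diff > 0) or partial
    loss (diff < 0). diff == 0 is never a tarSNP (no_effect).
    """
    if diff == 0:
        return EffectClass.NO_EFFECT
    if t_wt is None:
        return EffectClass.COMPLETE_GAIN
    if t_var is None:
        return EffectClass.COMPLETE_LOSS
    return EffectClass.PARTIAL_GAIN if diff > 0 else EffectClass.PARTIAL_LOSS


def normalize_diff(t_wt: Optional[float], t_var: Optional[float], diff: float) -> float:
    """diff divided by the larger score magnitude (absent -> 0).

    Sign is preserved; |result| <= 2 by the triangle inequality. Defined
    as 0 when both scores are zero.
    """
    denom = max(abs(t_wt) if t_wt is not None else 0.0,
                abs(t_var) if t_var is not None else 0.0)
    if denom == 0:
        return 0.0
    return diff / denom


def make_call(
    snp_id: str,
    gene_id: str,
    mirna_id: str,
    t_wt: Optional[float],
    t_var: Optional[float],
) -> Optional[TarSnpCall]:
    """Build the classified call for one scored pair; None if both absent."""
    if t_wt is None and t_var is None:
        return None
    diff = compute_diff(t_wt, t_var)
    return TarSnpCall(
        snp_id=snp_id,
        gene_id=gene_id,
        mirna_id=mirna_id,
        t_wt=t_wt,
        t_var=t_var,
        diff=diff,
        norm_diff=normalize_diff(t_wt, t_var, diff),
        effect_class=classify_effect(t_wt, t_var, diff),
    )


def is_tarsnp(call: TarSnpCall, min_abs_diff: float = 0.0) -> bool:
    """True for energy-changing calls passing the |diff| floor."""
    return call.effect_class is not EffectClass.NO_EFFECT and abs(call.diff) >= min_abs_diff


def rank_tarsnps(calls: list[TarSnpCall]) -> list[TarSnpCall]:
    """Priority order: descending |norm_diff|, then |diff|, then ids."""
    return sorted(
        calls,
        key=lambda c: (-abs(c.norm_diff), -abs(c.diff), c.snp_id, c.mirna_id, c.gene_id),
    )
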