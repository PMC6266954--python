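"""Map signed association results of a validated pair to an interaction type.

The biological readout: a miRNA that degrades its target mRNA shows up as
miRNA-gene anti-correlation; a miRNA that blocks translation leaves the
transcript intact (positive or null miRNA-gene association) but suppresses
the protein (gene-protein anti-correlation).  Because transcript and
protein abundances are imperfect proxies for each other, an anti-correlated
gene-protein leg under an anti-correlated miRNA-gene leg is still read as
degradation.  Pairs with no protein data cannot distinguish translation
inhibition and are starred.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

from statsmodels.stats.multitest import multipletests

from .globaltest import PairAssociation, Sign


class InteractionCall(str, Enum):
    DEGRADATION = "degradation"
    INHIBITION = "inhibition"
    NO_INTERACTION = "no_interaction"
    NO_INTERACTION_STAR = "no_interaction*"
    NO_EVIDENCE = "no_evidence"
    UNTESTABLE = "untestable"


#: Sign pattern -> call when both association legs pass the significance gate.
_SIGN_TABLE = {
    (Sign.NEGATIVE, Sign.POSITIVE): InteractionCall.DEGRADATION,
    (Sign.NEGATIVE, Sign.NEGATIVE): InteractionCall.DEGRADATION,
    (Sign.POSITIVE, Sign.NEGATIVE): InteractionCall.INHIBITION,
    (Sign.POSITIVE, Sign.POSITIVE): InteractionCall.NO_INTERACTION,
}


@dataclass(frozen=True)
class ClassificationConfig:
    alpha: float = 0.05
    mt_correction: str = "none"  # none | bh
    require_both_significant: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mt_correction not in ("none", "bh"):
            raise ValueError(f"unknown mt_correction {self.mt_correction!r}")


def _significant(assoc: PairAssociation, alpha: float) -> bool:
    return (
        assoc.testable
        and assoc.sign is not Sign.ZERO
        and assoc.p_value is not None
        and assoc.p_value <= alpha
    )


def classify_interaction(
    mg: PairAssociation,
    gp: Optional[PairAssociation],
    config: ClassificationConfig = ClassificationConfig(),
) -> InteractionCall:
    """Type one validated pair from its miRNA-gene and gene-protein tests.

    mg is the miRNA-gene association; gp is the gene-protein association or
    None when no protein data exists for the gene.  Pairs failing the
    significance gate are ``no_evidence``; degenerate inputs (constant
    profiles, zero cross-products) are ``untestable``.
    """
    if mg.untestable or (gp is not None and gp.untestable):
        return InteractionCall.UNTESTABLE
    mg_sig = _significant(mg, config.alpha)
    if not mg_sig:
        return InteractionCall.NO_EVIDENCE

    def _protein_absent_call() -> InteractionCall:
        if mg.sign is Sign.NEGATIVE:
            return InteractionCall.DEGRADATION
        return InteractionCall.NO_INTERACTION_STAR

    if gp is None:
        return _protein_absent_call()
    gp_sig = _significant(gp, config.alpha)
    if not gp_sig:
        if config.require_both_significant:
            return InteractionCall.NO_EVIDENCE
        # fall back to the protein-absent reading of the miRNA-gene leg
        return _protein_absent_call()
    return _SIGN_TABLE[(mg.sign, gp.sign)]


def apply_multiple_testing(
    pairs: Sequence[PairAssociation], method: str = "none"
) -> list[PairAssociation]:
    """Benjamini-Hochberg adjust p-values across one test family.

    Untestable pairs pass through unchanged and do not enter the family.
    """
    if method == "none":
        return list(pairs)
    if method != "bh":
        raise ValueError(f"unknown multiple-testing method {method!r}")
    testable_idx = [i for i, p in enumerate(pairs) if p.testable]
    if not testable_idx:
        return list(pairs)
    raw = [pairs[i].p_value for i in testable_idx]
    adjusted = multipletests(raw, method="fdr_bh")[1]
    out = list(pairs)
    for i, adj in zip(testable_idx, adjusted):
        out[i] = replace(pairs[i], p_value=float(min(adj, 1.0)))
    return out
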