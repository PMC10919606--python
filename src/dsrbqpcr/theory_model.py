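"""Theoretical template amplification percentages and assay-ratio tables.

The theoretical model is deliberately binary: a mixture member with at
most one mismatch per primer amplifies at 100% efficiency, one with
more than one mismatch does not amplify at all.  The theoretical
template amplification percentage of a mixture under an assay is then
simply 100 x the summed relative abundances of its amplifiable members
— independent of total concentration.

Assay pairs are compared by the ratio of their percentages; a ratio of
four or more (or one quarter or less) exceeds the study's four-fold
difference criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import pandas as pd

from .mixture_design import MixtureDesign
from .primer_match import AmplifiabilityMatrix

__all__ = [
    "FOURFOLD",
    "TheoreticalResult",
    "RatioComparison",
    "exceeds_fourfold",
    "theoretical_amp_pct",
    "ratio_table",
    "results_frame",
]

FOURFOLD = 4.0


def exceeds_fourfold(ratio: float) -> bool:
    """Boundary-inclusive four-fold rule: ratio >= 4 or <= 1/4."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return ratio >= FOURFOLD or ratio <= 1.0 / FOURFOLD


@dataclass(frozen=True)
class TheoreticalResult:
    gbtm_name: str
    primer_set: str
    theoretical_pct: float
    amplifiable_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not -1e-9 <= self.theoretical_pct <= 100 + 1e-9:
            raise ValueError("percentage out of [0, 100]")


@dataclass(frozen=True)
class RatioComparison:
    numerator_set: str
    denominator_set: str
    gbtm_name: str
    ratio: float | None  # None when the denominator percentage is 0
    exceeds_fourfold: bool | None


def theoretical_amp_pct(
    design: MixtureDesign,
    amplifiability: AmplifiabilityMatrix,
    primer_set: str,
) -> TheoreticalResult:
    """100 x summed relative abundances of the assay's amplifiable members."""
    if primer_set not in amplifiability.set_names:
        raise ValueError(f"unknown primer set {primer_set!r}")
    missing = set(design.template_ids) - set(amplifiability.template_ids)
    if missing:
        raise ValueError(f"design templates absent from matrix: {sorted(missing)}")
    amp_ids = tuple(
        t for t in design.template_ids if amplifiability.amplifiable(t, primer_set)
    )
    pct = 100.0 * design.fraction_of(amp_ids)
    return TheoreticalResult(
        gbtm_name=design.name,
        primer_set=primer_set,
        theoretical_pct=pct,
        amplifiable_ids=amp_ids,
    )


def ratio_table(results: Sequence[TheoreticalResult]) -> list[RatioComparison]:
    """All ordered assay-pair percentage ratios, per mixture.

    A zero denominator leaves the ratio undefined (``None``) rather than
    infinite; the four-fold flag is undefined with it.
    """
    by_gbtm: dict[str, list[TheoreticalResult]] = {}
    for r in results:
        by_gbtm.setdefault(r.gbtm_name, []).append(r)
    out: list[RatioComparison] = []
    for gbtm, rs in by_gbtm.items():
        if len(rs) < 2:
            raise ValueError(f"{gbtm}: need at least two assays to compare")
        for a, b in permutations(rs, 2):
            if b.theoretical_pct == 0:
                out.append(RatioComparison(a.primer_set, b.primer_set, gbtm, None, None))
            else:
                ratio = a.theoretical_pct / b.theoretical_pct
                # a zero numerator is an unbounded-fold difference
                flag = True if ratio == 0 else exceeds_fourfold(ratio)
                out.append(
                    RatioComparison(a.primer_set, b.primer_set, gbtm, ratio, flag)
                )
    return out


def results_frame(results: Sequence[TheoreticalResult]) -> pd.DataFrame:
    """Per-assay theoretical percentages as a tidy table."""
    return pd.DataFrame(
        {
            "gbtm": r.gbtm_name,
            "set": r.primer_set,
            "theoretical_pct": r.theoretical_pct,
            "n_amplifiable": len(r.amplifiable_ids),
        }
        for r in results
    )
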