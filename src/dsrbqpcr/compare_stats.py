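"""Empirical amplification percentages and the study's comparison statistics.

The empirical amplification percentage of a mixture under an assay is
the quantified copy number as a fraction of the total template copies
added to the reaction.  Two families of comparisons are drawn:

* theory vs. empirical (per assay and mixture condition): one-sample
  t-test of the log10 replicate quantifications against the log10 of
  the theoretically expected copy number;
* assay vs. assay (per mixture condition): paired t-test of log10
  replicate quantifications, paired by replicate index.

All tests run on the log10 scale because qPCR error is multiplicative.
Raw p-values are Benjamini–Hochberg adjusted within each report panel
(one family per figure-analogue panel), and a comparison is called
significant only when the adjusted p-value is below 0.05 AND the
compared quantities differ at least four-fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .theory_model import TheoreticalResult, exceeds_fourfold

__all__ = [
    "ALPHA",
    "EmpiricalResult",
    "ComparisonResult",
    "empirical_amp_pct",
    "one_sample_test",
    "paired_test",
    "bh_adjust",
    "significance_call",
    "study_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class EmpiricalResult:
    """Replicate quantifications of one (mixture, assay) condition."""

    gbtm_name: str
    primer_set: str
    replicate_quants: tuple[float, ...]
    input_total: float
    condition: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicate_quants:
            raise ValueError("empty replicate list")
        if self.input_total <= 0:
            raise ValueError("input_total must be positive")
        object.__setattr__(self, "replicate_quants", tuple(self.replicate_quants))
        object.__setattr__(self, "condition", dict(self.condition))

    @property
    def empirical_pct(self) -> float:
        return 100.0 * float(np.mean(self.replicate_quants)) / self.input_total


@dataclass(frozen=True)
class ComparisonResult:
    kind: str  # "theory_vs_empirical" | "assay_vs_assay"
    labels: tuple[str, ...]
    fold_ratio: float
    p_raw: float
    p_adj: float
    significant: bool


def empirical_amp_pct(
    replicate_quants: Sequence[float],
    input_total: float,
    *,
    gbtm_name: str = "",
    primer_set: str = "",
    condition: Mapping[str, object] | None = None,
) -> EmpiricalResult:
    """Quantified copies as a percentage of total template copies added."""
    return EmpiricalResult(
        gbtm_name=gbtm_name,
        primer_set=primer_set,
        replicate_quants=tuple(replicate_quants),
        input_total=input_total,
        condition=condition or {},
    )


def _log10(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("log10 tests require positive copy numbers")
    return np.log10(arr)


def one_sample_test(replicate_quants: Sequence[float], reference_value: float) -> float:
    """Two-sided one-sample t-test of log10 quants against log10(reference).

    Degenerate zero-variance replicates give p = 1 when they equal the
    reference and p = 0 (the limiting value) when they do not.
    """
    x = _log10(replicate_quants)
    if len(x) < 2:
        raise ValueError("need at least 2 replicates")
    mu0 = math.log10(reference_value)
    if np.ptp(x) == 0.0:
        return 1.0 if x[0] == mu0 else 0.0
    return float(stats.ttest_1samp(x, popmean=mu0).pvalue)


def paired_test(quants_a: Sequence[float], quants_b: Sequence[float]) -> float:
    """Two-sided paired t-test on the log10 scale, paired by replicate."""
    a, b = _log10(quants_a), _log10(quants_b)
    if len(a) != len(b):
        raise ValueError("paired test requires equal-length replicate lists")
    if len(a) < 2:
        raise ValueError("need at least 2 replicate pairs")
    diffs = a - b
    if np.ptp(diffs) == 0.0:
        return 1.0 if diffs[0] == 0.0 else 0.0
    return float(stats.ttest_rel(a, b).pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significance_call(fold_ratio: float, p_adj: float) -> bool:
    """Significant iff p_adj < 0.05 AND the four-fold criterion is met."""
    return bool(p_adj < ALPHA and exceeds_fourfold(fold_ratio))


def _finalize_panel(rows: list[dict]) -> pd.DataFrame:
    """Apply BH within one panel and attach significance calls."""
    panel = pd.DataFrame(rows)
    if panel.empty:
        return panel
    panel["p_adj"] = bh_adjust(panel["p_raw"].to_numpy())
    panel["significant"] = [
        significance_call(r, p) for r, p in zip(panel["ratio"], panel["p_adj"])
    ]
    return panel


def study_report(
    theory: Sequence[TheoreticalResult],
    empirical: Sequence[EmpiricalResult],
) -> dict[str, pd.DataFrame]:
    """Comparison tables for the two figure-analogue panel families.

    ``theory_vs_empirical_<conc>``: theoretical percentage / empirical
    percentage per (mixture, assay), one-sample t against the expected
    copies. ``assay_vs_assay_<conc>``: empirical ratio between each
    assay pair per mixture, paired t-test.  BH is applied within each
    panel. Mixture conditions missing from either side are skipped (and
    listed under ``"unmatched"``).
    """
    theory_by_key = {(t.gbtm_name, t.primer_set): t for t in theory}
    emp_by_key = {(e.gbtm_name, e.primer_set): e for e in empirical}
    concentrations = sorted(
        {str(e.condition.get("concentration", "all")) for e in empirical}
    )
    report: dict[str, pd.DataFrame] = {}
    unmatched: list[tuple[str, str]] = []

    for conc in concentrations:
        emp_panel = [
            e for e in empirical if str(e.condition.get("concentration", "all")) == conc
        ]
        rows = []
        for e in emp_panel:
            t = theory_by_key.get((e.gbtm_name, e.primer_set))
            if t is None:
                unmatched.append((e.gbtm_name, e.primer_set))
                continue
            if t.theoretical_pct == 0 or e.empirical_pct == 0:
                continue  # ratio undefined; nothing to test
            expected_copies = t.theoretical_pct / 100.0 * e.input_total
            rows.append(
                {
                    "condition": e.gbtm_name,
                    "comparison": e.primer_set,
                    "theoretical_pct": t.theoretical_pct,
                    "empirical_pct": e.empirical_pct,
                    "ratio": t.theoretical_pct / e.empirical_pct,
                    "p_raw": one_sample_test(e.replicate_quants, expected_copies),
                }
            )
        report[f"theory_vs_empirical_{conc}"] = _finalize_panel(rows)

        rows = []
        gbtms = sorted({e.gbtm_name for e in emp_panel})
        for gbtm in gbtms:
            here = [e for e in emp_panel if e.gbtm_name == gbtm]
            for ea, eb in combinations(here, 2):
                if len(ea.replicate_quants) != len(eb.replicate_quants):
                    unmatched.append((gbtm, f"{ea.primer_set} vs {eb.primer_set}"))
                    continue
                rows.append(
                    {
                        "condition": gbtm,
                        "comparison": f"{ea.primer_set} vs {eb.primer_set}",
                        "ratio": ea.empirical_pct / eb.empirical_pct,
                        "p_raw": paired_test(ea.replicate_quants, eb.replicate_quants),
                    }
                )
        report[f"assay_vs_assay_{conc}"] = _finalize_panel(rows)

    report["unmatched"] = pd.DataFrame(unmatched, columns=["condition", "comparison"])
    return report
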