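"""Artificial template-mixture (gBTM) design: evenness and dominance control.

A gBlock template mixture (gBTM) combines the panel templates at
relative abundances drawn from a log-normal profile.  Evenness is
controlled by the log-normal scale sigma (larger sigma = more uneven;
sigma = 0 degenerates to a perfectly even community) and dominance by
which amplifiability group — "common" (amplified by every assay) or
"rare" (amplified by a single assay) — receives the largest fractions.

Profiles are deterministic by default: the n fractions are taken at the
midpoint quantiles (i - 0.5)/n of LogNormal(mu, sigma), so designs are
exactly reproducible and sigma controls evenness monotonically.  A
seeded random-draw mode is retained for sensitivity analyses.

The full study grid crosses 2 dominance modes x 3 sigma values x 2
total-concentration conditions (high ~1e8 and low ~1e5 copies/uL) at
fixed richness 12.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .primer_match import TemplateSeq

__all__ = [
    "MixtureDesign",
    "ConcentrationCondition",
    "HIGH_CONCENTRATION",
    "LOW_CONCENTRATION",
    "STUDY_SIGMAS",
    "STUDY_MU",
    "lognormal_abundance_profile",
    "pielou_evenness",
    "assign_dominance",
    "copies_per_template",
    "study_grid",
]

STUDY_MU = 1.0
STUDY_SIGMAS = (1.0, 2.0, 5.0)

_GROUP_PRIORITY = {
    "common": ["common", "less common", "rare", "none"],
    "rare": ["rare", "less common", "common", "none"],
}


@dataclass(frozen=True)
class ConcentrationCondition:
    label: str
    copies_per_ul: float

    def __post_init__(self) -> None:
        if self.copies_per_ul <= 0:
            raise ValueError("copies_per_ul must be positive")


HIGH_CONCENTRATION = ConcentrationCondition("high", 1e8)
LOW_CONCENTRATION = ConcentrationCondition("low", 1e5)


@dataclass(frozen=True)
class MixtureDesign:
    """One designed gBTM: template -> relative abundance, plus metadata."""

    name: str
    abundances: Mapping[str, float]
    dominance_mode: str
    mu: float
    sigma: float
    total_concentration: float
    seed: int = 0

    def __post_init__(self) -> None:
        abund = dict(self.abundances)
        if not abund:
            raise ValueError(f"{self.name}: empty abundance map")
        if any(v <= 0 for v in abund.values()):
            raise ValueError(f"{self.name}: all fractions must be > 0")
        total = math.fsum(abund.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"{self.name}: fractions sum to {total!r}, not 1")
        if self.total_concentration <= 0:
            raise ValueError(f"{self.name}: total_concentration must be > 0")
        object.__setattr__(self, "abundances", abund)

    @property
    def template_ids(self) -> list[str]:
        return list(self.abundances)

    def fraction_of(self, ids: Sequence[str]) -> float:
        return math.fsum(self.abundances[t] for t in ids if t in self.abundances)


def lognormal_abundance_profile(
    n: int,
    mu: float = STUDY_MU,
    sigma: float = 1.0,
    *,
    random_draw: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """n relative abundances from LogNormal(mu, sigma), descending, sum 1.

    Deterministic midpoint-quantile rule by default: values are taken at
    probabilities (i - 0.5)/n.  sigma = 0 yields the perfectly even
    profile 1/n.  ``random_draw=True`` draws i.i.d. instead (seeded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0 and not random_draw:
        return np.full(n, 1.0 / n)
    if random_draw:
        rng = np.random.default_rng(seed)
        raw = rng.lognormal(mean=mu, sigma=sigma, size=n)
    else:
        probs = (np.arange(1, n + 1) - 0.5) / n
        raw = np.exp(mu + sigma * stats.norm.ppf(probs))
    fractions = raw / raw.sum()
    return np.sort(fractions)[::-1]


def pielou_evenness(fractions: Sequence[float]) -> float:
    """Pielou's J = Shannon H / ln(n); 1 for a perfectly even community."""
    p = np.asarray(fractions, dtype=float)
    p = p / p.sum()
    if len(p) < 2:
        return 1.0
    h = -np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))
    return float(h / np.log(len(p)))


def _labels_for(
    templates: Sequence[TemplateSeq], group_labels: Mapping[str, str] | None
) -> dict[str, str]:
    out = {}
    for t in templates:
        label = (group_labels or {}).get(t.id, t.group_label)
        if label is None:
            raise ValueError(f"{t.id}: no group label available")
        out[t.id] = label
    return out


def assign_dominance(
    profile: Sequence[float],
    templates: Sequence[TemplateSeq],
    mode: str,
    *,
    group_labels: Mapping[str, str] | None = None,
    mu: float = STUDY_MU,
    sigma: float = float("nan"),
    total_concentration: float = HIGH_CONCENTRATION.copies_per_ul,
    seed: int = 0,
    name: str | None = None,
    within_group_order: Mapping[str, Sequence[str]] | None = None,
) -> MixtureDesign:
    """Map the sorted abundance profile onto templates by dominance mode.

    The largest fractions go to the named group's members (the "common"
    group for ``mode="common"``, the "rare" group for ``mode="rare"``),
    then down the group priority.  Within a group the order is a seeded
    permutation unless ``within_group_order`` pins an explicit ranking
    (as the packaged study scenarios do); the multiset of fractions is
    never altered, only the assignment permutation.
    """
    if mode not in _GROUP_PRIORITY:
        raise ValueError(f"unknown dominance mode {mode!r}")
    if len(profile) != len(templates):
        raise ValueError("profile length must equal template count")
    labels = _labels_for(templates, group_labels)
    groups: dict[str, list[str]] = {}
    for tid, lab in labels.items():
        groups.setdefault(lab, []).append(tid)
    if not groups.get(mode):
        raise ValueError(f"dominance group {mode!r} has no members")

    rng = np.random.default_rng(seed)
    ordered_ids: list[str] = []
    for group in _GROUP_PRIORITY[mode]:
        members = sorted(groups.get(group, []))
        if not members:
            continue
        if within_group_order and group in within_group_order:
            pinned = [t for t in within_group_order[group] if t in members]
            if sorted(pinned) != members:
                raise ValueError(f"within_group_order for {group!r} must cover {members}")
            members = pinned
        else:
            members = [members[i] for i in rng.permutation(len(members))]
        ordered_ids.extend(members)

    fractions = np.sort(np.asarray(profile, dtype=float))[::-1]
    fractions = fractions / fractions.sum()
    abundances = {tid: float(f) for tid, f in zip(ordered_ids, fractions)}
    return MixtureDesign(
        name=name or f"{mode}-gbtm",
        abundances=abundances,
        dominance_mode=mode,
        mu=mu,
        sigma=sigma,
        total_concentration=total_concentration,
        seed=seed,
    )


def copies_per_template(
    design: MixtureDesign,
    reaction_volume_ul: float = 1.0,
    *,
    poisson: bool = False,
    seed: int | None = None,
) -> dict[str, float]:
    """Absolute template copies in one reaction.

    copies_i = fraction_i x total_concentration x template volume.  With
    ``poisson=True`` each count is replaced by a seeded Poisson draw to
    model low-template sampling stochasticity (unbiased in expectation).
    """
    if reaction_volume_ul <= 0:
        raise ValueError("reaction volume must be positive")
    expected = {
        tid: frac * design.total_concentration * reaction_volume_ul
        for tid, frac in design.abundances.items()
    }
    if not poisson:
        return expected
    rng = np.random.default_rng(seed)
    return {tid: float(rng.poisson(v)) for tid, v in expected.items()}


def study_grid(
    templates: Sequence[TemplateSeq],
    *,
    group_labels: Mapping[str, str] | None = None,
    mu: float = STUDY_MU,
    sigmas: Sequence[float] = STUDY_SIGMAS,
    modes: Sequence[str] = ("common", "rare"),
    conditions: Sequence[ConcentrationCondition] = (HIGH_CONCENTRATION, LOW_CONCENTRATION),
    seed: int = 0,
    within_group_order: Mapping[str, Sequence[str]] | None = None,
) -> list[MixtureDesign]:
    """The full experimental design grid (default 2 x 3 x 2 = 12 gBTMs)."""
    designs = []
    for mode in modes:
        for sigma in sigmas:
            profile = lognormal_abundance_profile(len(templates), mu, sigma)
            for cond in conditions:
                designs.append(
                    assign_dominance(
                        profile,
                        templates,
                        mode,
                        group_labels=group_labels,
                        mu=mu,
                        sigma=sigma,
                        total_concentration=cond.copies_per_ul,
                        seed=seed,
                        name=f"{mode}_sigma{sigma:g}_{cond.label}",
                        within_group_order=within_group_order,
                    )
                )
    return designs
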