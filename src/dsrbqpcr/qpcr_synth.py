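"""Synthetic qPCR fluorescence generator.

Replaces the real-time instrument: given initial template copies and a
per-template per-cycle efficiency, each cycle multiplies every template
pool by ``1 + E * saturation`` where ``saturation = max(0, 1 - total /
plateau_capacity)`` — a shared-resource logistic plateau.  Total
fluorescence is molecule count times a signal scale plus a constant +
linearly drifting baseline and Gaussian readout noise.  This kinetic
model is the package's own; it is chosen because it produces
Richards-shaped amplification curves and a log-linear Cy0 calibration,
the two properties the downstream quantification requires.

Per-template efficiencies follow the mismatch class of the template
under an assay (perfect / one-mismatch / blocked), with an override
table for idiosyncratic template-assay pairs whose real amplification
is not predicted by mismatch count alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .primer_match import AmplifiabilityMatrix

__all__ = [
    "EfficiencyModel",
    "ReactionSpec",
    "AmplificationCurve",
    "DEFAULT_DILUTION_LEVELS",
    "simulate_reaction",
    "efficiency_from_matrix",
    "simulate_dilution_series",
    "curves_to_frame",
    "frame_to_curves",
]

#: Standard dilution series, copies/uL: 2.34e2 ... 2.34e8 in 10-fold steps
#: (0.1 ng/uL of a 390 bp fragment diluted 10-fold down to 1e-7 ng/uL).
DEFAULT_DILUTION_LEVELS: tuple[float, ...] = tuple(2.34e2 * 10.0 ** k for k in range(7))


@dataclass(frozen=True)
class EfficiencyModel:
    """Mismatch-class -> per-cycle efficiency, with per-pair overrides."""

    e_perfect: float = 0.95
    e_one_mm: float = 0.6
    e_blocked: float = 0.0
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, e in (
            ("e_perfect", self.e_perfect),
            ("e_one_mm", self.e_one_mm),
            ("e_blocked", self.e_blocked),
            *(((f"override {k}", v) for k, v in self.overrides.items())),
        ):
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{name}: efficiency {e} outside [0, 1]")
        object.__setattr__(self, "overrides", dict(self.overrides))


@dataclass(frozen=True)
class ReactionSpec:
    """Everything needed to simulate one reaction's fluorescence curve."""

    template_copies: Mapping[str, float]
    efficiency: Mapping[str, float]
    cycles: int = 35
    plateau_capacity: float = 1e11
    fluorescence_scale: float = 3e-8
    baseline_const: float = 100.0
    baseline_drift: float = 0.5  # fluorescence units per cycle
    noise_sd: float = 15.0  # ~0.5% of the ~3000-unit plateau amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.plateau_capacity <= 0:
            raise ValueError("plateau_capacity must be > 0")
        for tid, n0 in self.template_copies.items():
            if n0 < 0:
                raise ValueError(f"{tid}: negative initial copies")
        for tid, e in self.efficiency.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"{tid}: efficiency {e} outside [0, 1]")
        object.__setattr__(self, "template_copies", dict(self.template_copies))
        object.__setattr__(self, "efficiency", dict(self.efficiency))


@dataclass
class AmplificationCurve:
    """Per-cycle fluorescence readings of one reaction."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycle and fluorescence vectors differ in length")
        if np.any(np.diff(self.cycles) <= 0):
            raise ValueError("cycles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.cycles)


def simulate_reaction(spec: ReactionSpec) -> AmplificationCurve:
    """Simulate one reaction under the shared-capacity logistic model."""
    rng = np.random.default_rng(spec.seed)
    ids = list(spec.template_copies)
    n = np.array([spec.template_copies[t] for t in ids], dtype=float)
    e = np.array([spec.efficiency.get(t, 0.0) for t in ids], dtype=float)
    cycles = np.arange(1, spec.cycles + 1)
    total = np.empty(spec.cycles)
    for i in range(spec.cycles):
        saturation = max(0.0, 1.0 - n.sum() / spec.plateau_capacity)
        n = n * (1.0 + e * saturation)
        total[i] = n.sum()
    fluor = (
        spec.fluorescence_scale * total
        + spec.baseline_const
        + spec.baseline_drift * cycles
    )
    if spec.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, spec.noise_sd, size=spec.cycles)
    return AmplificationCurve(cycles=cycles, fluorescence=fluor)


def efficiency_from_matrix(
    amplifiability: AmplifiabilityMatrix,
    set_name: str,
    model: EfficiencyModel | None = None,
) -> dict[str, float]:
    """Per-template efficiencies under one assay.

    The mismatch class is the worse of the best forward and reverse
    mismatch counts (matching the per-primer <=1 MM screen): 0 ->
    ``e_perfect``, 1 -> ``e_one_mm``, unamplifiable -> ``e_blocked``.
    Overrides keyed by (template_id, set_name) take precedence.
    """
    model = model or EfficiencyModel()
    out: dict[str, float] = {}
    for tid in amplifiability.template_ids:
        key = (tid, set_name)
        if key in model.overrides:
            out[tid] = model.overrides[key]
            continue
        cell = amplifiability.cells[(tid, set_name)]
        if not cell.amplifiable:
            out[tid] = model.e_blocked
        else:
            worst = max(cell.forward_mm or 0, cell.reverse_mm or 0)
            out[tid] = model.e_perfect if worst == 0 else model.e_one_mm
    return out


def simulate_dilution_series(
    copies_levels: Sequence[float] = DEFAULT_DILUTION_LEVELS,
    *,
    replicates: int = 3,
    template_volume_ul: float = 1.0,
    efficiency: float = 0.95,
    seed: int = 0,
    template_id: str = "standard",
    **spec_kwargs,
) -> list[AmplificationCurve]:
    """Standard dilution series: one curve per level x replicate.

    Each reaction receives ``level x template_volume_ul`` copies of a
    single perfect-match standard template.  Metadata records the level
    (copies/uL), initial copies and replicate index.
    """
    if any(level <= 0 for level in copies_levels):
        raise ValueError("all dilution levels must be positive")
    seeds = np.random.SeedSequence(seed).generate_state(len(copies_levels) * replicates)
    curves = []
    i = 0
    for level in copies_levels:
        for rep in range(replicates):
            n0 = level * template_volume_ul
            spec = ReactionSpec(
                template_copies={template_id: n0},
                efficiency={template_id: efficiency},
                seed=int(seeds[i] % (2**31)),
                **spec_kwargs,
            )
            curve = simulate_reaction(spec)
            curve.metadata = {
                "condition": f"std_{level:.3g}",
                "copies_per_ul": level,
                "initial_copies": n0,
                "replicate": rep,
            }
            curves.append(curve)
            i += 1
    return curves


def curves_to_frame(curves: Sequence[AmplificationCurve]) -> pd.DataFrame:
    """Long-format table: condition, well, replicate, cycle, fluorescence."""
    frames = []
    for well, c in enumerate(curves):
        frames.append(
            pd.DataFrame(
                {
                    "condition": c.metadata.get("condition", ""),
                    "well": well,
                    "replicate": c.metadata.get("replicate", 0),
                    "cycle": c.cycles,
                    "fluorescence": c.fluorescence,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_curves(frame: pd.DataFrame) -> list[AmplificationCurve]:
    """Rebuild curves from the long-format table (instrument-export shape)."""
    curves = []
    for well, grp in frame.groupby("well", sort=True):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                cycles=grp["cycle"].to_numpy(),
                fluorescence=grp["fluorescence"].to_numpy(),
                metadata={
                    "condition": grp["condition"].iloc[0],
                    "replicate": int(grp["replicate"].iloc[0]),
                },
            )
        )
    return curves
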