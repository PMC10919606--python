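"""End-to-end study driver: panel -> designs -> simulation -> quantification
-> comparison report.

``run_study`` executes the whole in-silico experiment on the packaged
synthetic panel (or any user-supplied templates/assays): build the
amplifiability matrix, design the mixture grid, calibrate one standard
curve per assay from a simulated dilution series, simulate replicate
mixture reactions with mismatch-class efficiencies, quantify every well
through its assay's calibration, and assemble the theory-vs-empirical
and assay-vs-assay comparison panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import synthetic_assay
from .compare_stats import EmpiricalResult, study_report
from .cy0_quant import StandardCurve, fit_richards, quantify_sample, standard_curve_from_series
from .mixture_design import (
    HIGH_CONCENTRATION,
    LOW_CONCENTRATION,
    STUDY_SIGMAS,
    ConcentrationCondition,
    MixtureDesign,
    copies_per_template,
    study_grid,
)
from .primer_match import AmplifiabilityMatrix, PrimerSet, TemplateSeq, amplifiability_matrix
from .qpcr_synth import (
    EfficiencyModel,
    ReactionSpec,
    efficiency_from_matrix,
    simulate_dilution_series,
    simulate_reaction,
)
from .theory_model import TheoreticalResult, results_frame, theoretical_amp_pct

__all__ = ["StudyResult", "run_study", "simulate_mixture_quants", "low_efficiency_rare_model"]


@dataclass
class StudyResult:
    amplifiability: AmplifiabilityMatrix
    designs: list[MixtureDesign]
    theory: list[TheoreticalResult]
    empirical: list[EmpiricalResult]
    standard_curves: dict[str, StandardCurve]
    standard_fit_tables: dict[str, pd.DataFrame]
    report: dict[str, pd.DataFrame]
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def theory_frame(self) -> pd.DataFrame:
        return results_frame(self.theory)

    def empirical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gbtm": e.gbtm_name,
                "set": e.primer_set,
                "empirical_pct": e.empirical_pct,
                "input_total": e.input_total,
                "n_replicates": len(e.replicate_quants),
                **e.condition,
            }
            for e in self.empirical
        )


def low_efficiency_rare_model() -> EfficiencyModel:
    """Efficiency model of the packaged poorly-amplified-rare scenario."""
    return EfficiencyModel(overrides=synthetic_assay.low_efficiency_rare_overrides())


def simulate_mixture_quants(
    design: MixtureDesign,
    efficiencies: Mapping[str, float],
    sc: StandardCurve,
    *,
    replicates: int = 3,
    seed: int = 0,
    template_volume_ul: float = 1.0,
    poisson_copies: bool = False,
    **spec_kwargs,
) -> list[float]:
    """Replicate copy estimates for one (mixture, assay) condition.

    Each replicate simulates a fresh reaction, fits the Richards model,
    extracts Cy0 and inverts the assay's standard curve.  Wells whose
    fit does not converge yield no estimate.
    """
    seeds = np.random.SeedSequence(seed).generate_state(2 * replicates)
    quants: list[float] = []
    for rep in range(replicates):
        copies = copies_per_template(
            design,
            template_volume_ul,
            poisson=poisson_copies,
            seed=int(seeds[2 * rep] % (2**31)),
        )
        spec = ReactionSpec(
            template_copies=copies,
            efficiency=dict(efficiencies),
            seed=int(seeds[2 * rep + 1] % (2**31)),
            **spec_kwargs,
        )
        fit = fit_richards(simulate_reaction(spec))
        if not fit.converged:
            continue
        quants.append(
            quantify_sample(fit.cy0, sc, sample_id=f"{design.name}:{rep}").estimated_copies_per_ul
        )
    return quants


def run_study(
    seed: int = 0,
    *,
    templates: Sequence[TemplateSeq] | None = None,
    primer_sets: Sequence[PrimerSet] | None = None,
    efficiency_model: EfficiencyModel | None = None,
    replicates: int = 3,
    sigmas: Sequence[float] = STUDY_SIGMAS,
    modes: Sequence[str] = ("common", "rare"),
    conditions: Sequence[ConcentrationCondition] = (HIGH_CONCENTRATION, LOW_CONCENTRATION),
    within_group_order: Mapping[str, Sequence[str]] | None = None,
    max_mm: int = 1,
    out_dir: str | Path | None = None,
    **spec_kwargs,
) -> StudyResult:
    """Run the full in-silico study grid and assemble the report tables.

    By default the packaged synthetic panel, the default efficiency
    model and the 2 dominance x len(sigmas) x 2 concentration grid are
    used; the packaged scenarios pin ``within_group_order`` and pass the
    low-efficiency override model.  ``seed`` drives every stochastic
    component (noise, replicate seeds) through a single SeedSequence.
    """
    templates = list(templates) if templates is not None else synthetic_assay.gblock_panel()
    psets = list(primer_sets) if primer_sets is not None else synthetic_assay.primer_sets()
    model = efficiency_model or EfficiencyModel()

    matrix = amplifiability_matrix(templates, psets, max_mm=max_mm)
    designs = study_grid(
        templates,
        group_labels=matrix.group_labels,
        sigmas=sigmas,
        modes=modes,
        conditions=conditions,
        seed=seed,
        within_group_order=within_group_order,
    )

    ss = np.random.SeedSequence(seed)
    std_seeds = ss.generate_state(len(psets))
    mix_ss = ss.spawn(1)[0]
    mix_seeds = mix_ss.generate_state(len(designs) * len(psets))

    standard_curves: dict[str, StandardCurve] = {}
    standard_fit_tables: dict[str, pd.DataFrame] = {}
    for pset, s in zip(psets, std_seeds):
        series = simulate_dilution_series(
            replicates=replicates, efficiency=model.e_perfect,
            seed=int(s % (2**31)), **spec_kwargs,
        )
        sc, table = standard_curve_from_series(series)
        standard_curves[pset.name] = sc
        standard_fit_tables[pset.name] = table

    conc_label = {c.copies_per_ul: c.label for c in conditions}
    theory: list[TheoreticalResult] = []
    empirical: list[EmpiricalResult] = []
    dropped: list[tuple[str, str]] = []
    i = 0
    for design in designs:
        for pset in psets:
            theory.append(theoretical_amp_pct(design, matrix, pset.name))
            eff = efficiency_from_matrix(matrix, pset.name, model)
            quants = simulate_mixture_quants(
                design, eff, standard_curves[pset.name],
                replicates=replicates, seed=int(mix_seeds[i] % (2**31)),
                **spec_kwargs,
            )
            i += 1
            if len(quants) < 2:
                dropped.append((design.name, pset.name))
                continue
            empirical.append(
                EmpiricalResult(
                    gbtm_name=design.name,
                    primer_set=pset.name,
                    replicate_quants=tuple(quants),
                    input_total=design.total_concentration,
                    condition={
                        "dominance": design.dominance_mode,
                        "sigma": design.sigma,
                        "concentration": conc_label.get(
                            design.total_concentration, f"{design.total_concentration:g}"
                        ),
                    },
                )
            )

    report = study_report(theory, empirical)
    result = StudyResult(
        amplifiability=matrix,
        designs=designs,
        theory=theory,
        empirical=empirical,
        standard_curves=standard_curves,
        standard_fit_tables=standard_fit_tables,
        report=report,
        dropped=dropped,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: StudyResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.amplifiability.to_table().to_csv(out_dir / "amplifiability.tsv", sep="\t", index=False)
    result.theory_frame().to_csv(out_dir / "theory_pct.tsv", sep="\t", index=False)
    result.empirical_frame().to_csv(out_dir / "empirical_pct.tsv", sep="\t", index=False)
    sc_rows = [
        {
            "set": name, "slope": sc.slope, "intercept": sc.intercept,
            "r_squared": sc.r_squared, "level_min": sc.level_range[0],
            "level_max": sc.level_range[1], "detection_limit": sc.detection_limit,
        }
        for name, sc in result.standard_curves.items()
    ]
    pd.DataFrame(sc_rows).to_csv(out_dir / "standard_curves.tsv", sep="\t", index=False)
    for panel, frame in result.report.items():
        frame.to_csv(out_dir / f"report_{panel}.tsv", sep="\t", index=False)
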