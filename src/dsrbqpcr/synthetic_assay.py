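"""Synthetic dsrB assay panel: three primer sets and twelve gBlock stand-ins.

The study system is the beta subunit of the dissimilatory sulfite
reductase gene (*dsrB*), quantified with three assays of increasing
degeneracy.  The specific assay uses the published DSRp2060F
(``CAACATCGTYCAYACCCAGGG``, degeneracy 4) and DSR4R
(``GTGTAGCAGTTACCGCA``, degeneracy 1) primers.  The two degenerate
assays and all twelve 390-bp template sequences in this module are
SYNTHETIC stand-ins: the real oligo mixes and gBlock sequences live in
supplementary tables that are not redistributed here, so we engineer a
panel that reproduces the documented design constraints exactly —

* forward/reverse mix degeneracies 4/1, 77/10 and 98/29;
* twelve 390-bp templates, each carrying at least one assay's binding
  sites within the 1-mismatch tolerance;
* amplifiable-template counts 7, 8 and 9 for the specific, intermediate
  and most degenerate assay respectively;
* a Venn partition of 4 "common" (all three assays), 4 "less common"
  (exactly two) and 4 "rare" (exactly one) templates.

Binding sites are planted into seeded random backgrounds and the panel
generator verifies, with the package's own matcher, that every template
matches its designed membership pattern and nothing else.  A handful of
sites are planted with a deliberate single mismatch to exercise the
1-MM branch of the classifier (gb03's forward site for the most
degenerate assay mirrors the real panel's "≤1 MM but poorly amplified"
gBlock 3).
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import reverse_complement

from .primer_match import (
    IUPAC_SETS,
    DegeneratePrimer,
    PrimerSet,
    TemplateSeq,
    is_amplifiable,
)

__all__ = [
    "SPECIFIC_ASSAY",
    "INTERMEDIATE_ASSAY",
    "DEGENERATE_ASSAY",
    "ASSAY_NAMES",
    "MEMBERSHIP",
    "SUPERCLUSTERS",
    "RARE_DOMINANCE_ORDER",
    "primer_sets",
    "gblock_panel",
    "low_efficiency_rare_overrides",
]

SPECIFIC_ASSAY = "DSRp2060F/DSR4R"
INTERMEDIATE_ASSAY = "DSR1728Fmix/DSR4Rmix"
DEGENERATE_ASSAY = "DSR1762Fmix/DSR2107Rmix"
ASSAY_NAMES = (SPECIFIC_ASSAY, INTERMEDIATE_ASSAY, DEGENERATE_ASSAY)

TEMPLATE_LENGTH = 390
_PANEL_SEED = 20240307  # fixed: the panel is a reference object, not a knob

#: Designed assay membership of each template (which assays can amplify it).
MEMBERSHIP: dict[str, frozenset[str]] = {
    "gb01": frozenset(ASSAY_NAMES),
    "gb02": frozenset(ASSAY_NAMES),
    "gb03": frozenset({DEGENERATE_ASSAY}),
    "gb04": frozenset(ASSAY_NAMES),
    "gb05": frozenset(ASSAY_NAMES),
    "gb06": frozenset({INTERMEDIATE_ASSAY}),
    "gb07": frozenset({DEGENERATE_ASSAY}),
    "gb08": frozenset({INTERMEDIATE_ASSAY, DEGENERATE_ASSAY}),
    "gb09": frozenset({INTERMEDIATE_ASSAY, DEGENERATE_ASSAY}),
    "gb10": frozenset({SPECIFIC_ASSAY, INTERMEDIATE_ASSAY}),
    "gb11": frozenset({SPECIFIC_ASSAY, DEGENERATE_ASSAY}),
    "gb12": frozenset({SPECIFIC_ASSAY}),
}

#: Phylogenetic supercluster flavour labels (metadata only, never computed).
SUPERCLUSTERS = {
    "gb01": "Deltaproteobacteria",
    "gb02": "Deltaproteobacteria",
    "gb03": "Nitrospirae",
    "gb04": "Firmicutes",
    "gb05": "Deltaproteobacteria",
    "gb06": "Environmental cluster 1",
    "gb07": "Archaeoglobus",
    "gb08": "Deltaproteobacteria",
    "gb09": "Firmicutes",
    "gb10": "Deltaproteobacteria",
    "gb11": "Environmental cluster 1",
    "gb12": "Deltaproteobacteria",
}

#: Within-rare-group dominance ranking used by the packaged scenario:
#: the templates amplifiable only by a degenerate assay take the top
#: abundances, as in the real panel where gBlocks 3/6/7 dominate the
#: rare-dominated mixtures.
RARE_DOMINANCE_ORDER = ["gb06", "gb03", "gb07", "gb12"]

# Deliberate 1-mismatch plants: (template, assay, which site).  The real
# panel's binding sites carried assorted 0/1-MM combinations; these plants
# exercise the 1-MM branch of the classifier and the reduced one-mismatch
# efficiency class of the simulator.
_ONE_MM_PLANTS = {
    ("gb02", SPECIFIC_ASSAY, "forward"),
    ("gb05", INTERMEDIATE_ASSAY, "reverse"),
    ("gb03", DEGENERATE_ASSAY, "forward"),
    ("gb08", DEGENERATE_ASSAY, "reverse"),
    ("gb09", DEGENERATE_ASSAY, "forward"),
}

# Plus-strand slot (start) of each assay's planted forward/reverse site.
_SLOTS = {
    SPECIFIC_ASSAY: {"forward": 20, "reverse": 330},
    INTERMEDIATE_ASSAY: {"forward": 50, "reverse": 300},
    DEGENERATE_ASSAY: {"forward": 80, "reverse": 270},
}


def _variant(core: str, disc: str | None, subs: dict[int, str]) -> str:
    """Member oligo: optional discriminator base at position 0 + IUPAC subs."""
    s = list(core)
    if disc is not None:
        s[0] = disc
    for pos, code in subs.items():
        s[pos] = code
    return "".join(s)


def primer_sets() -> list[PrimerSet]:
    """The three assays, in increasing order of degeneracy (4/1, 77/10, 98/29).

    Mix members of the synthetic mixes differ concretely at their first
    position, so their expansions are disjoint and the union degeneracy
    is the sum of the member degeneracies.
    """
    specific = PrimerSet(
        name=SPECIFIC_ASSAY,
        forward_mix=(
            DegeneratePrimer("DSRp2060F", "CAACATCGTYCAYACCCAGGG", "forward"),
        ),
        reverse_mix=(DegeneratePrimer("DSR4R", "GTGTAGCAGTTACCGCA", "reverse"),),
    )

    gf = "ACTGGAAGCACGGCGAGACC"  # synthetic forward core, intermediate assay
    gr = "GTGGTGGTACATGGCGTCCA"  # synthetic reverse core
    intermediate = PrimerSet(
        name=INTERMEDIATE_ASSAY,
        forward_mix=(  # 64 + 8 + 4 + 1 = 77 distinct oligos
            DegeneratePrimer("DSR1728F-a", _variant(gf, "A", {5: "N", 10: "N", 15: "N"}), "forward"),
            DegeneratePrimer("DSR1728F-b", _variant(gf, "C", {5: "N", 10: "R"}), "forward"),
            DegeneratePrimer("DSR1728F-c", _variant(gf, "G", {5: "R", 10: "Y"}), "forward"),
            DegeneratePrimer("DSR1728F-d", _variant(gf, "T", {}), "forward"),
        ),
        reverse_mix=(  # 8 + 2 = 10
            DegeneratePrimer("DSR4R-a", _variant(gr, "A", {6: "N", 12: "R"}), "reverse"),
            DegeneratePrimer("DSR4R-b", _variant(gr, "C", {6: "Y"}), "reverse"),
        ),
    )

    rf = "CGTCAAGTTCGGCGACTTCA"  # synthetic forward core, most degenerate assay
    rr = "CCAGTTGCCGTTCATCGGTA"  # synthetic reverse core
    degenerate = PrimerSet(
        name=DEGENERATE_ASSAY,
        forward_mix=(  # 64 + 32 + 2 = 98
            DegeneratePrimer("DSR1762F-a", _variant(rf, "A", {4: "N", 9: "N", 14: "N"}), "forward"),
            DegeneratePrimer("DSR1762F-b", _variant(rf, "C", {4: "N", 9: "N", 14: "Y"}), "forward"),
            DegeneratePrimer("DSR1762F-c", _variant(rf, "G", {4: "W"}), "forward"),
        ),
        reverse_mix=(  # 16 + 8 + 4 + 1 = 29
            DegeneratePrimer("DSR2107R-a", _variant(rr, "A", {5: "N", 11: "N"}), "reverse"),
            DegeneratePrimer("DSR2107R-b", _variant(rr, "C", {5: "N", 11: "R"}), "reverse"),
            DegeneratePrimer("DSR2107R-c", _variant(rr, "G", {5: "R", 11: "Y"}), "reverse"),
            DegeneratePrimer("DSR2107R-d", _variant(rr, "T", {}), "reverse"),
        ),
    )
    return [specific, intermediate, degenerate]


def _concretize(iupac_seq: str, rng: np.random.Generator) -> str:
    """One concrete expansion of an IUPAC string (seeded choice per position)."""
    out = []
    for ch in iupac_seq:
        bases = sorted(IUPAC_SETS[ch])
        out.append(bases[int(rng.integers(len(bases)))])
    return "".join(out)


def _shared_concrete_positions(mix: tuple[DegeneratePrimer, ...]) -> list[int]:
    """Positions where every mix member has the same single concrete base."""
    length = len(mix[0])
    positions = []
    for i in range(length):
        codes = {m.sequence[i] for m in mix}
        if len(codes) == 1 and len(IUPAC_SETS[next(iter(codes))]) == 1:
            positions.append(i)
    return positions


def _plant_one_mismatch(
    oligo: str, mix: tuple[DegeneratePrimer, ...], rng: np.random.Generator
) -> str:
    """Mutate one position shared concretely by all members -> exactly 1 MM."""
    pos_choices = [p for p in _shared_concrete_positions(mix) if p >= 2]
    pos = pos_choices[int(rng.integers(len(pos_choices)))]
    old = oligo[pos]
    alternatives = [b for b in "ACGT" if b != old]
    new = alternatives[int(rng.integers(3))]
    return oligo[:pos] + new + oligo[pos + 1 :]


def _build_template(
    tid: str,
    membership: frozenset[str],
    sets_by_name: dict[str, PrimerSet],
    rng: np.random.Generator,
) -> TemplateSeq:
    bases = np.array(list("ACGT"))
    seq = list("".join(bases[rng.integers(4, size=TEMPLATE_LENGTH)]))
    for assay in sorted(membership):
        pset = sets_by_name[assay]
        for which, mix in (("forward", pset.forward_mix), ("reverse", pset.reverse_mix)):
            member = mix[0]
            oligo = _concretize(member.sequence, rng)
            if (tid, assay, which) in _ONE_MM_PLANTS:
                oligo = _plant_one_mismatch(oligo, mix, rng)
            site = oligo if which == "forward" else reverse_complement(oligo)
            start = _SLOTS[assay][which]
            seq[start : start + len(site)] = list(site)
    return TemplateSeq(id=tid, sequence="".join(seq), supercluster_label=SUPERCLUSTERS[tid])


def gblock_panel(max_attempts: int = 50) -> list[TemplateSeq]:
    """The 12 synthetic 390-bp gBlock templates.

    Each template's designed assay membership is verified with the
    package matcher at the study's 1-mismatch tolerance; a background
    draw that accidentally creates or destroys a binding pattern is
    redrawn (deterministically seeded, so the panel is reproducible).
    """
    rng = np.random.default_rng(_PANEL_SEED)
    sets = {p.name: p for p in primer_sets()}
    panel: list[TemplateSeq] = []
    for tid, membership in MEMBERSHIP.items():
        for _ in range(max_attempts):
            tpl = _build_template(tid, membership, sets, rng)
            observed = frozenset(
                name for name, p in sets.items() if is_amplifiable(tpl, p, max_mm=1).amplifiable
            )
            if observed == membership:
                panel.append(tpl)
                break
        else:
            raise RuntimeError(f"could not realize designed membership for {tid}")
    return panel


def low_efficiency_rare_overrides() -> dict[tuple[str, str], float]:
    """Packaged scenario: poorly amplified rare dominants.

    The rare-group templates that only the degenerate assays can bind
    amplify far below the perfect-match efficiency despite passing the
    ≤1-MM screen, emulating the real panel's gBlocks 3/6/7 whose
    recovery was only a few percent of input.  Per-cycle efficiency 0.5
    (vs 0.95 for a clean match) yields that few-percent recovery regime
    against a perfect-efficiency standard curve.
    """
    return {
        ("gb06", INTERMEDIATE_ASSAY): 0.5,
        ("gb03", DEGENERATE_ASSAY): 0.5,
        ("gb07", DEGENERATE_ASSAY): 0.5,
    }
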