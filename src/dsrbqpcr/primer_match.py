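"""IUPAC-aware degenerate-primer matching and template amplifiability.

A degenerate primer is a mixture of oligonucleotides written as a single
string over the IUPAC nucleotide alphabet (``R`` = A/G, ``Y`` = C/T, ...,
``N`` = any).  This module expands such primers, counts the distinct
oligos a primer mix comprises (its *degeneracy*), searches templates for
binding sites under a mismatch tolerance, and classifies templates as
amplifiable by a primer set when a convergent forward/reverse site pair
exists with at most ``max_mm`` mismatches per primer.

Mismatch semantics: a primer position *matches* a template base when the
base is a member of the primer position's IUPAC set — primer-side
ambiguity is coverage, never a mismatch.  For a primer mix the mismatch
count of a window is the minimum over the mix members (any constituent
oligo in the tube can prime).  The search is ungapped and every position
is weighted equally; a per-position weight hook is exposed for 3'-end
sensitivity studies but defaults to uniform.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

__all__ = [
    "IUPAC_SETS",
    "DegeneratePrimer",
    "PrimerSet",
    "TemplateSeq",
    "BindingHit",
    "AmplifiabilityCell",
    "AmplifiabilityMatrix",
    "expand_iupac",
    "mix_degeneracy",
    "count_mismatches",
    "find_binding_sites",
    "is_amplifiable",
    "amplifiability_matrix",
]

#: IUPAC code -> frozenset of concrete bases (from Biopython's table,
#: restricted to the 15 standard nucleotide codes — no X/gap).
IUPAC_SETS: dict[str, frozenset[str]] = {
    code: frozenset(bases)
    for code, bases in ambiguous_dna_values.items()
    if code in "ACGTRYSWKMBDHVN"
}

GROUP_COMMON = "common"
GROUP_LESS_COMMON = "less common"
GROUP_RARE = "rare"
GROUP_NONE = "none"


def _validate_iupac(sequence: str, *, name: str = "primer") -> str:
    if not sequence:
        raise ValueError(f"{name}: empty sequence")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise ValueError(
                f"{name}: non-IUPAC character {ch!r} at position {pos}"
            )
    return seq


@dataclass(frozen=True)
class DegeneratePrimer:
    """One primer of a mix, written in the IUPAC alphabet (5'->3')."""

    name: str
    sequence: str
    orientation: Literal["forward", "reverse"]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_iupac(self.sequence, name=self.name)
        )
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"{self.name}: bad orientation {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        """Number of distinct concrete oligos this primer encodes."""
        d = 1
        for ch in self.sequence:
            d *= len(IUPAC_SETS[ch])
        return d


@dataclass(frozen=True)
class PrimerSet:
    """A qPCR assay: a forward and a reverse primer mix."""

    name: str
    forward_mix: tuple[DegeneratePrimer, ...]
    reverse_mix: tuple[DegeneratePrimer, ...]
    amplicon_min: int | None = None
    amplicon_max: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "forward_mix", tuple(self.forward_mix))
        object.__setattr__(self, "reverse_mix", tuple(self.reverse_mix))
        if not self.forward_mix or not self.reverse_mix:
            raise ValueError(f"{self.name}: both mixes must be non-empty")
        for p in self.forward_mix:
            if p.orientation != "forward":
                raise ValueError(f"{self.name}: {p.name} is not a forward primer")
        for p in self.reverse_mix:
            if p.orientation != "reverse":
                raise ValueError(f"{self.name}: {p.name} is not a reverse primer")

    @property
    def forward_degeneracy(self) -> int:
        return mix_degeneracy(self.forward_mix)

    @property
    def reverse_degeneracy(self) -> int:
        return mix_degeneracy(self.reverse_mix)


@dataclass(frozen=True)
class TemplateSeq:
    """An unambiguous template sequence (e.g. one synthetic gBlock)."""

    id: str
    sequence: str
    group_label: str | None = None
    supercluster_label: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(seq) - set("ACGT")
        if bad:
            raise ValueError(f"{self.id}: ambiguity codes not allowed: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BindingHit:
    """One primer binding site on a template (plus-strand coordinates)."""

    template_id: str
    primer_name: str
    strand: Literal["plus", "minus"]
    start: int  # 0-based, half-open
    end: int
    mismatches: int


def expand_iupac(primer: DegeneratePrimer | str) -> set[str]:
    """All concrete A/C/G/T oligos a degenerate primer encodes.

    The set size equals the product of per-position ambiguity-set sizes.
    """
    seq = primer.sequence if isinstance(primer, DegeneratePrimer) else _validate_iupac(primer)
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return {"".join(p) for p in itertools.product(*pools)}


def mix_degeneracy(mix: Iterable[DegeneratePrimer | str]) -> int:
    """Distinct concrete oligos in the union of all mix members' expansions."""
    mix = list(mix)
    if not mix:
        raise ValueError("empty primer mix")
    union: set[str] = set()
    for member in mix:
        union |= expand_iupac(member)
    return len(union)


def count_mismatches(
    primer_seq: str,
    template_window: str,
    weights: Sequence[float] | None = None,
) -> int | float:
    """Mismatches between an IUPAC primer and an equal-length template window.

    A position mismatches when the template base is not in the primer
    position's IUPAC set.  ``weights`` (same length) scores each
    mismatching position; default is 1 per position.
    """
    primer_seq = _validate_iupac(primer_seq)
    template_window = template_window.upper()
    if len(primer_seq) != len(template_window):
        raise ValueError(
            f"length mismatch: primer {len(primer_seq)} vs window {len(template_window)}"
        )
    if weights is not None and len(weights) != len(primer_seq):
        raise ValueError("weights length must equal primer length")
    total: int | float = 0
    for i, (p, t) in enumerate(zip(primer_seq, template_window)):
        if t not in IUPAC_SETS[p]:
            total += 1 if weights is None else weights[i]
    return total


def find_binding_sites(
    template: TemplateSeq,
    primer: DegeneratePrimer,
    max_mm: int,
    weights: Sequence[float] | None = None,
) -> list[BindingHit]:
    """All binding sites of one primer on a template within ``max_mm``.

    Forward primers are scanned along the plus strand; reverse primers
    along the reverse complement, with hit coordinates reported back on
    the plus strand (``strand="minus"``).  Hits are sorted by plus-strand
    position, then mismatch count.  A template shorter than the primer
    yields an empty list.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    L = len(primer)
    n = len(template)
    if n < L:
        return []
    scan_seq = (
        template.sequence
        if primer.orientation == "forward"
        else reverse_complement(template.sequence)
    )
    strand = "plus" if primer.orientation == "forward" else "minus"
    hits: list[BindingHit] = []
    for i in range(n - L + 1):
        mm = count_mismatches(primer.sequence, scan_seq[i : i + L], weights)
        if mm <= max_mm:
            if strand == "plus":
                start = i
            else:  # map back from reverse-complement coordinates
                start = n - (i + L)
            hits.append(
                BindingHit(
                    template_id=template.id,
                    primer_name=primer.name,
                    strand=strand,
                    start=start,
                    end=start + L,
                    mismatches=int(mm) if weights is None else mm,
                )
            )
    hits.sort(key=lambda h: (h.start, h.mismatches))
    return hits


def _mix_hits(
    template: TemplateSeq, mix: Iterable[DegeneratePrimer], max_mm: int
) -> list[BindingHit]:
    hits: list[BindingHit] = []
    for member in mix:
        hits.extend(find_binding_sites(template, member, max_mm))
    hits.sort(key=lambda h: (h.start, h.mismatches))
    return hits


@dataclass(frozen=True)
class AmplifiabilityCell:
    """Amplifiability verdict for one (template, primer set) pair."""

    amplifiable: bool
    forward_mm: int | None = None
    reverse_mm: int | None = None
    forward_hit: BindingHit | None = None
    reverse_hit: BindingHit | None = None

    @property
    def amplicon_span(self) -> tuple[int, int] | None:
        if self.forward_hit is None or self.reverse_hit is None:
            return None
        return (self.forward_hit.start, self.reverse_hit.end)


def is_amplifiable(
    template: TemplateSeq, primer_set: PrimerSet, max_mm: int = 1
) -> AmplifiabilityCell:
    """Can a primer set amplify a template, allowing ``max_mm`` per primer?

    True iff a forward-mix hit and a reverse-mix hit exist in convergent
    orientation (forward site strictly upstream of the reverse site's
    plus-strand location), each within the mismatch tolerance.  Among
    valid pairs the minimal total-mismatch, outermost pair is reported;
    optional amplicon-length bounds on the set are honoured.
    """
    fwd_hits = _mix_hits(template, primer_set.forward_mix, max_mm)
    rev_hits = [
        h for h in _mix_hits(template, primer_set.reverse_mix, max_mm)
        if h.strand == "minus"
    ]
    best: tuple | None = None
    for f in fwd_hits:
        for r in rev_hits:
            if f.start >= r.start:  # not convergent
                continue
            length = r.end - f.start
            if primer_set.amplicon_min is not None and length < primer_set.amplicon_min:
                continue
            if primer_set.amplicon_max is not None and length > primer_set.amplicon_max:
                continue
            key = (f.mismatches + r.mismatches, f.start, -r.end)
            if best is None or key < best[0]:
                best = (key, f, r)
    if best is None:
        return AmplifiabilityCell(amplifiable=False)
    _, f, r = best
    return AmplifiabilityCell(
        amplifiable=True,
        forward_mm=f.mismatches,
        reverse_mm=r.mismatches,
        forward_hit=f,
        reverse_hit=r,
    )


@dataclass
class AmplifiabilityMatrix:
    """Template x primer-set amplifiability with the Venn-style grouping.

    ``group_labels`` classifies each template by how many assays can
    amplify it: all sets -> "common", exactly two -> "less common",
    exactly one -> "rare".  Templates amplifiable by no set violate the
    panel design intent and are collected in ``unamplified`` (and
    labelled "none").
    """

    template_ids: list[str]
    set_names: list[str]
    cells: dict[tuple[str, str], AmplifiabilityCell]
    group_labels: dict[str, str] = field(default_factory=dict)
    unamplified: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_sets = len(self.set_names)
        for tid in self.template_ids:
            member_of = [
                s for s in self.set_names if self.cells[(tid, s)].amplifiable
            ]
            k = len(member_of)
            if k == 0:
                self.group_labels[tid] = GROUP_NONE
                if tid not in self.unamplified:
                    self.unamplified.append(tid)
            elif k == n_sets:
                self.group_labels[tid] = GROUP_COMMON
            elif k == 1:
                self.group_labels[tid] = GROUP_RARE
            else:
                self.group_labels[tid] = GROUP_LESS_COMMON

    def amplifiable(self, template_id: str, set_name: str) -> bool:
        return self.cells[(template_id, set_name)].amplifiable

    def amplifiable_ids(self, set_name: str) -> list[str]:
        return [t for t in self.template_ids if self.amplifiable(t, set_name)]

    def column_sums(self) -> dict[str, int]:
        """Amplifiable template count per assay (the Venn circle sizes)."""
        return {s: len(self.amplifiable_ids(s)) for s in self.set_names}

    def venn_partition(self) -> dict[str, frozenset[str]]:
        """Template id -> the set of assays that can amplify it."""
        return {
            tid: frozenset(
                s for s in self.set_names if self.amplifiable(tid, s)
            )
            for tid in self.template_ids
        }

    def to_frame(self) -> pd.DataFrame:
        """Boolean template x assay matrix."""
        return pd.DataFrame(
            [
                [self.amplifiable(t, s) for s in self.set_names]
                for t in self.template_ids
            ],
            index=self.template_ids,
            columns=self.set_names,
        )

    def to_table(self) -> pd.DataFrame:
        """Tidy per-pair report: mismatch counts, verdict, group label."""
        rows = []
        for t in self.template_ids:
            for s in self.set_names:
                c = self.cells[(t, s)]
                rows.append(
                    {
                        "template_id": t,
                        "set": s,
                        "forward_mm": c.forward_mm,
                        "reverse_mm": c.reverse_mm,
                        "amplifiable": c.amplifiable,
                        "group_label": self.group_labels[t],
                    }
                )
        return pd.DataFrame(rows)


def amplifiability_matrix(
    templates: Sequence[TemplateSeq],
    primer_sets: Sequence[PrimerSet],
    max_mm: int = 1,
) -> AmplifiabilityMatrix:
    """Full amplifiability matrix over all (template, primer set) pairs."""
    if not templates or not primer_sets:
        raise ValueError("templates and primer_sets must be non-empty")
    cells = {
        (t.id, s.name): is_amplifiable(t, s, max_mm)
        for t in templates
        for s in primer_sets
    }
    return AmplifiabilityMatrix(
        template_ids=[t.id for t in templates],
        set_names=[s.name for s in primer_sets],
        cells=cells,
    )
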