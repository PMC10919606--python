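"""FASTA and table I/O.

Primer FASTA records encode mix membership and orientation in the
header: ``>name|set|F`` or ``>name|set|R``.  Template FASTA records are
plain ``>id`` with an optional ``group=...`` / ``supercluster=...``
key-value description.  Real instrument exports mapped to the
long-format curve table (condition, well, replicate, cycle,
fluorescence) can be substituted anywhere the simulator's output is
consumed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .primer_match import DegeneratePrimer, PrimerSet, TemplateSeq

__all__ = [
    "write_primer_fasta",
    "read_primer_fasta",
    "write_template_fasta",
    "read_template_fasta",
    "write_curve_csv",
    "read_curve_csv",
]


def write_primer_fasta(primer_sets: Sequence[PrimerSet], path: str | Path) -> None:
    records = []
    for pset in primer_sets:
        for orient, mix in (("F", pset.forward_mix), ("R", pset.reverse_mix)):
            for p in mix:
                records.append(
                    SeqRecord(Seq(p.sequence), id=f"{p.name}|{pset.name}|{orient}", description="")
                )
    SeqIO.write(records, str(path), "fasta")


def read_primer_fasta(path: str | Path) -> list[PrimerSet]:
    """Rebuild primer sets from the ``>name|set|F/R`` header convention."""
    mixes: dict[str, dict[str, list[DegeneratePrimer]]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            name, set_name, orient = rec.id.split("|")
        except ValueError as err:
            raise ValueError(f"bad primer header {rec.id!r}; expected name|set|F/R") from err
        orientation = {"F": "forward", "R": "reverse"}[orient]
        if set_name not in mixes:
            mixes[set_name] = {"forward": [], "reverse": []}
            order.append(set_name)
        mixes[set_name][orientation].append(
            DegeneratePrimer(name=name, sequence=str(rec.seq), orientation=orientation)
        )
    return [
        PrimerSet(name=s, forward_mix=tuple(mixes[s]["forward"]), reverse_mix=tuple(mixes[s]["reverse"]))
        for s in order
    ]


def write_template_fasta(templates: Sequence[TemplateSeq], path: str | Path) -> None:
    records = []
    for t in templates:
        desc = []
        if t.group_label:
            # description fields are whitespace-delimited key=value pairs
            desc.append(f"group={t.group_label.replace(' ', '_')}")
        if t.supercluster_label:
            desc.append(f"supercluster={t.supercluster_label}")
        records.append(SeqRecord(Seq(t.sequence), id=t.id, description=" ".join(desc)))
    SeqIO.write(records, str(path), "fasta")


def read_template_fasta(path: str | Path) -> list[TemplateSeq]:
    templates = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = dict(
            part.split("=", 1)
            for part in rec.description.split()[1:]
            if "=" in part
        )
        templates.append(
            TemplateSeq(
                id=rec.id,
                sequence=str(rec.seq),
                group_label=kv["group"].replace("_", " ") if "group" in kv else None,
                supercluster_label=kv.get("supercluster"),
            )
        )
    return templates


def write_curve_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_curve_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"condition", "well", "replicate", "cycle", "fluorescence"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    return frame
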