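"""Assay degeneracy accounting and in-silico template coverage.

Expands the three dsrB primer sets, counts the distinct oligos each mix
comprises, classifies every panel template as amplifiable/not per assay
at the 1-mismatch tolerance, and derives the common / less common /
rare grouping (the Venn partition).  Writes the amplifiability report
and the panel FASTA files under results/.
"""

import sys
from pathlib import Path

from dsrbqpcr import amplifiability_matrix
from dsrbqpcr import io as dio
from dsrbqpcr import synthetic_assay

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    psets = synthetic_assay.primer_sets()
    panel = synthetic_assay.gblock_panel()

    print("Primer mix degeneracies (forward/reverse):")
    for p in psets:
        print(f"  {p.name}: {p.forward_degeneracy}/{p.reverse_degeneracy}")

    matrix = amplifiability_matrix(panel, psets, max_mm=1)
    sums = matrix.column_sums()
    print("\nAmplifiable templates per assay (of 12, <=1 MM per primer):")
    for name, k in sums.items():
        print(f"  {name}: {k}")
    groups = matrix.group_labels
    for label in ("common", "less common", "rare"):
        members = sorted(t for t, g in groups.items() if g == label)
        print(f"  {label}: {', '.join(members)}")
    if matrix.unamplified:
        print(f"  WARNING: templates amplified by no assay: {matrix.unamplified}")

    matrix.to_table().to_csv(OUT / "amplifiability.tsv", sep="\t", index=False)
    dio.write_primer_fasta(psets, OUT / "primers.fasta")
    dio.write_template_fasta(panel, OUT / "gblocks.fasta")
    print(f"\nWrote {OUT / 'amplifiability.tsv'} and panel FASTA files.")


if __name__ == "__main__":
    sys.exit(main())
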