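"""Degenerate-primer expansion, mismatch search and amplifiability."""

import itertools

import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings
from hypothesis import strategies as st

from dsrbqpcr.primer_match import (
    IUPAC_SETS,
    DegeneratePrimer,
    PrimerSet,
    TemplateSeq,
    amplifiability_matrix,
    count_mismatches,
    expand_iupac,
    find_binding_sites,
    is_amplifiable,
    mix_degeneracy,
)

IUPAC_ALPHABET = "ACGTRYSWKMBDHVN"


def fwd(seq, name="p"):
    return DegeneratePrimer(name, seq, "forward")


class TestExpansion:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ACGT", {"ACGT"}),
            ("RY", {"AC", "AT", "GC", "GT"}),
            ("N", {"A", "C", "G", "T"}),
        ],
    )
    def test_expansion_examples(self, seq, expected):
        assert expand_iupac(seq) == expected

    def test_bad_character_reports_position(self):
        with pytest.raises(ValueError, match="position 2"):
            expand_iupac("ACXG")

    @given(st.text(alphabet=IUPAC_ALPHABET, min_size=1, max_size=12))
    @settings(max_examples=100, derandomize=True)
    def test_degeneracy_is_product_of_position_sizes(self, seq):
        product = 1
        for ch in seq:
            product *= len(IUPAC_SETS[ch])
        assert len(expand_iupac(seq)) == product
        assert fwd(seq).degeneracy == product

    def test_mix_degeneracy_deduplicates_union(self):
        assert mix_degeneracy([fwd("ACGT")]) == 1
        # AY expands to {AC, AT}; AC is shared with the second member
        assert mix_degeneracy([fwd("AY"), fwd("AC")]) == 2

    def test_panel_mix_degeneracies(self, psets):
        degs = {p.name: (p.forward_degeneracy, p.reverse_degeneracy) for p in psets}
        assert degs == {
            "DSRp2060F/DSR4R": (4, 1),
            "DSR1728Fmix/DSR4Rmix": (77, 10),
            "DSR1762Fmix/DSR2107Rmix": (98, 29),
        }


class TestMismatchCounting:
    @pytest.mark.parametrize(
        "primer,window,mm",
        [("ACGT", "ACGT", 0), ("Y", "C", 0), ("Y", "G", 1), ("NNNN", "ACGT", 0)],
    )
    def test_examples(self, primer, window, mm):
        assert count_mismatches(primer, window) == mm

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            count_mismatches("ACG", "ACGT")

    @given(
        st.text(alphabet=IUPAC_ALPHABET, min_size=1, max_size=15),
        st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_symmetric_under_joint_reverse_complement(self, primer, data):
        window = data.draw(
            st.text(alphabet="ACGT", min_size=len(primer), max_size=len(primer))
        )
        assert count_mismatches(primer, window) == count_mismatches(
            reverse_complement(primer), reverse_complement(window)
        )


def brute_force_hits(template: str, primer: DegeneratePrimer, max_mm: int):
    """Independent oracle: enumerate every expanded oligo at every window."""
    oligos = expand_iupac(primer)
    scan = template if primer.orientation == "forward" else reverse_complement(template)
    L = len(primer)
    found = []
    for i in range(len(scan) - L + 1):
        window = scan[i : i + L]
        best = min(
            sum(a != b for a, b in zip(oligo, window)) for oligo in oligos
        )
        if best <= max_mm:
            start = i if primer.orientation == "forward" else len(template) - (i + L)
            found.append((start, best))
    return sorted(found)


class TestBindingSiteSearch:
    def test_exact_substring_found(self):
        tpl = TemplateSeq("t", "AAAA" + "CCGGTTAACC" + "GGGG")
        hits = find_binding_sites(tpl, fwd("CCGGTTAACC"), max_mm=0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].mismatches) == (4, 14, 0)

    def test_template_shorter_than_primer_is_empty(self):
        assert find_binding_sites(TemplateSeq("t", "ACGT"), fwd("ACGTACGT"), 1) == []

    def test_no_window_within_tolerance_is_empty(self):
        tpl = TemplateSeq("t", "A" * 50)
        assert find_binding_sites(tpl, fwd("CCCCCCCC"), max_mm=1) == []

    def test_reverse_primer_coordinates_on_plus_strand(self):
        site = "ACGTACGTACGT"
        tpl = TemplateSeq("t", "GG" + reverse_complement(site) + "TTTT")
        rev = DegeneratePrimer("r", site, "reverse")
        hits = find_binding_sites(tpl, rev, max_mm=0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].strand) == (2, 14, "minus")

    @pytest.mark.parametrize("orientation", ["forward", "reverse"])
    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_matches_brute_force_oracle(self, orientation, max_mm):
        import numpy as np

        rng = np.random.default_rng(7 + max_mm)
        bases = np.array(list("ACGT"))
        # mostly concrete primers with a few 2-fold codes keeps the oracle's
        # expansion small while still exercising ambiguity
        primer_alphabet = list("ACGT" "RY")
        for _ in range(40):
            tpl_seq = "".join(bases[rng.integers(4, size=int(rng.integers(50, 300)))])
            L = int(rng.integers(8, 25))
            pseq = "".join(
                primer_alphabet[int(i)]
                for i in rng.integers(len(primer_alphabet), size=L)
            )
            primer = DegeneratePrimer("p", pseq, orientation)
            tpl = TemplateSeq("t", tpl_seq)
            got = sorted((h.start, h.mismatches) for h in find_binding_sites(tpl, primer, max_mm))
            assert got == brute_force_hits(tpl_seq, primer, max_mm)

    def test_tolerance_superset_property(self):
        import numpy as np

        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        tpl = TemplateSeq("t", "".join(bases[rng.integers(4, size=200)]))
        primer = fwd("".join(bases[rng.integers(4, size=12)]))
        for k in (1, 2, 3):
            smaller = {(h.start, h.strand) for h in find_binding_sites(tpl, primer, k - 1)}
            larger = {(h.start, h.strand) for h in find_binding_sites(tpl, primer, k)}
            assert smaller <= larger


class TestAmplifiability:
    def test_forward_site_alone_is_not_amplifiable(self):
        f = fwd("ACGTACGTAC")
        r = DegeneratePrimer("r", "GGGGGGGGGG", "reverse")
        pset = PrimerSet("s", (f,), (r,))
        tpl = TemplateSeq("t", "TT" + "ACGTACGTAC" + "A" * 60)
        assert not is_amplifiable(tpl, pset, max_mm=1).amplifiable

    def test_convergent_pair_required(self):
        f = fwd("ACGTACGTAC")
        r = DegeneratePrimer("r", "TTTTCCCCAA", "reverse")
        rc_site = reverse_complement("TTTTCCCCAA")
        # reverse site upstream of forward site -> divergent, no amplicon
        tpl = TemplateSeq("t", rc_site + "TTAA" + "ACGTACGTAC" + "GG")
        assert not is_amplifiable(tpl, PrimerSet("s", (f,), (r,)), 1).amplifiable
        # reverse site downstream -> amplifiable
        tpl2 = TemplateSeq("t2", "GG" + "ACGTACGTAC" + "TTAA" + rc_site)
        cell = is_amplifiable(tpl2, PrimerSet("s", (f,), (r,)), 1)
        assert cell.amplifiable
        assert cell.amplicon_span == (2, 26)

    def test_panel_counts_seven_eight_nine(self, matrix):
        assert matrix.column_sums() == {
            "DSRp2060F/DSR4R": 7,
            "DSR1728Fmix/DSR4Rmix": 8,
            "DSR1762Fmix/DSR2107Rmix": 9,
        }

    def test_panel_group_partition(self, matrix):
        from collections import Counter

        counts = Counter(matrix.group_labels.values())
        assert counts == {"common": 4, "less common": 4, "rare": 4}
        assert matrix.unamplified == []

    def test_matrix_agrees_with_per_pair_calls(self, panel, psets, matrix):
        for t in panel:
            for p in psets:
                assert matrix.amplifiable(t.id, p.name) == is_amplifiable(t, p, 1).amplifiable

    def test_report_table_shape(self, matrix):
        table = matrix.to_table()
        assert len(table) == 12 * 3
        assert set(table.columns) == {
            "template_id", "set", "forward_mm", "reverse_mm", "amplifiable", "group_label",
        }
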