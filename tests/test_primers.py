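"""Degenerate-primer parsing, the 2^N mixing rule, and in-silico PCR."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from markerkit.primers import (
    INOSINE,
    AmpliconHit,
    PrimerMix,
    PrimerParseError,
    degeneracy_count,
    expand_variants,
    extract_amplicon_by_reference,
    in_silico_pcr,
    match_site,
    mix_volume,
    parse_primer,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(REVCOMP)[::-1]


class TestParsing:
    def test_bracket_group_and_length(self):
        p = parse_primer("TGCTTAGCGA[AG]GCGCCCAA", id="F2")
        assert p.length == 19
        assert sum(1 for pos in p.positions if len(pos) == 2) == 1
        assert p.positions[10] == frozenset("AG")

    def test_all_singleton(self):
        p = parse_primer("TCTTGAGTGAAGCTCCAGACTA", id="F1")
        assert p.length == 22
        assert all(len(pos) == 1 for pos in p.positions)

    def test_inline_iupac_and_inosine(self):
        p = parse_primer("T[I]ATGGTTGAAGCTCCDGAYTAYGG", id="Cel48_490F_I")
        assert p.length == 25
        assert p.positions[1] is INOSINE
        assert p.positions[16] == frozenset("AGT")  # D
        assert p.positions[19] == frozenset("CT")  # Y
        assert p.positions[22] == frozenset("CT")  # Y

    def test_bracket_equals_inline_code(self):
        assert parse_primer("AAAAAAAAA[AG]A").positions == parse_primer("AAAAAAAAARA").positions

    @pytest.mark.parametrize(
        "text",
        ["AAAAAAAAA[AG", "AAAAAAAAAA]", "AAAAAAAAA[]A", "AAAAAAAAAXA", "AAAAAAAAA[AX]"],
    )
    def test_malformed_notation_rejected(self, text):
        with pytest.raises(PrimerParseError):
            parse_primer(text)

    def test_parsed_lengths_match_printed_column(self, mix):
        import importlib.resources as res

        import pandas as pd

        with res.as_file(res.files("markerkit.data") / "cel48_mix2.tsv") as path:
            printed = pd.read_csv(path, sep="\t").set_index("id")
        for p in mix.primers:
            assert p.length == printed.loc[p.id, "length"]


class TestMixingRule:
    def test_degeneracy_counts(self, primer_by_id):
        assert degeneracy_count(primer_by_id["F6"]) == 3
        assert degeneracy_count(primer_by_id["F3"]) == 1  # two inosines ignored
        assert degeneracy_count(parse_primer("ACGTACGTACGT")) == 0

    def test_volumes(self, primer_by_id):
        assert mix_volume(primer_by_id["F6"]) == 8
        assert mix_volume(primer_by_id["R3"]) == 8
        assert mix_volume(primer_by_id["F1"]) == 1

    def test_forward_reverse_submixes_disjoint(self, mix):
        assert not {p.id for p in mix.forward} & {p.id for p in mix.reverse}

    def test_volume_is_power_of_two_of_count(self, mix):
        for p in mix.primers:
            assert mix_volume(p) == 2 ** degeneracy_count(p)


class TestExpansion:
    def test_single_two_base_position(self, primer_by_id):
        variants = expand_variants(primer_by_id["F2"])
        assert len(variants) == 2
        assert variants == sorted(variants)

    def test_f6_has_eight_variants(self, primer_by_id):
        assert len(expand_variants(primer_by_id["F6"])) == 8

    def test_inosine_kept_literal(self):
        p = parse_primer("T[I]ATGGTTGAAGCTCCDGAYTAYGG")
        variants = expand_variants(p)
        assert len(variants) == 12  # 3 x 2 x 2, inosine excluded
        assert all(v.count("I") == 1 for v in variants)

    def test_count_equals_product_of_set_sizes(self, mix):
        # brute-force oracle over the whole published cocktail
        for p in mix.primers:
            product = 1
            for pos in p.positions:
                product *= 1 if pos is INOSINE else len(pos)
            assert len(expand_variants(p)) == product
            assert len(set(expand_variants(p))) == product

    def test_expansion_cap(self):
        with pytest.raises(ValueError, match="exceed cap"):
            expand_variants(parse_primer("N" * 10), cap=4096)


class TestMatchSite:
    def test_self_match(self, primer_by_id):
        f1 = primer_by_id["F1"]
        assert match_site(f1, f1.text, max_mismatch=0) == [(0, "+", 0)]

    def test_degenerate_position_satisfied_by_either_base(self, primer_by_id):
        template = "GG" + "TGCTTAGCGAGGCGCCCAA" + "TT"
        hits = match_site(primer_by_id["F2"], template, max_mismatch=0)
        assert hits == [(2, "+", 0)]

    def test_mismatch_threshold_boundary(self, primer_by_id):
        f1 = primer_by_id["F1"]
        mutated = "G" + f1.text[1:]
        assert match_site(f1, mutated, max_mismatch=0) == []
        assert match_site(f1, mutated, max_mismatch=1) == [(0, "+", 1)]

    def test_empty_template(self, primer_by_id):
        assert match_site(primer_by_id["F1"], "", max_mismatch=2) == []

    def test_reverse_complement_strand_hit(self, primer_by_id):
        f1 = primer_by_id["F1"]
        template = "ACGT" + rc(f1.text) + "ACGT"
        assert match_site(f1, template, max_mismatch=0) == [(4, "-", 0)]

    def test_equivalence_with_variant_oracle(self, primer_by_id):
        """Exact matching equals brute-force window-vs-expanded-variant check."""
        import random

        rng = random.Random(42)
        for pid in ("F6", "R3", "F3"):
            p = primer_by_id[pid]
            template = "".join(rng.choice("ACGT") for _ in range(300))
            site = expand_variants(p)[0].replace("I", rng.choice("ACGT"))
            template = template[:100] + site + template[100:]
            variants = [v for v in expand_variants(p)]
            rc_variants = [rc(v.replace("I", "N")).replace("N", "I") for v in variants]

            def oracle(pats, tpl, k):
                hits = set()
                for off in range(len(tpl) - k + 1):
                    w = tpl[off : off + k]
                    for v in pats:
                        if all(c == "I" or c == b for c, b in zip(v, w)):
                            hits.add(off)
                            break
                return hits

            got = match_site(p, template, max_mismatch=0)
            assert {o for o, s, _ in got if s == "+"} == oracle(variants, template, len(p))
            assert {o for o, s, _ in got if s == "-"} == oracle(rc_variants, template, len(p))


class TestInSilicoPcr:
    def test_constructed_product(self, mix, primer_by_id):
        import random

        rng = random.Random(5)
        x = "".join(rng.choice("ACGT") for _ in range(344))
        template = primer_by_id["F1"].text + x + rc(primer_by_id["R6"].text)
        hits = in_silico_pcr(mix, template, max_mismatch=0)
        assert len(hits) == 1
        hit = hits[0]
        assert hit.amplicon_seq == x
        assert hit.inner_length == 344
        assert hit.mismatches == (0, 0)
        assert hit.strand == "+"

    def test_forward_site_only_no_product(self, mix, primer_by_id):
        template = "ACGT" * 30 + primer_by_id["F1"].text + "ACGT" * 100
        assert in_silico_pcr(mix, template, max_mismatch=0) == []

    def test_two_forward_sites_two_products(self, primer_by_id):
        import random

        rng = random.Random(9)
        f1, r6 = primer_by_id["F1"], primer_by_id["R6"]
        small = PrimerMix([f1, r6], name="pair")
        x1 = "".join(rng.choice("ACGT") for _ in range(150))
        x2 = "".join(rng.choice("ACGT") for _ in range(150))
        template = f1.text + x1 + f1.text + x2 + rc(r6.text)
        hits = in_silico_pcr(small, template, max_mismatch=0, min_len=100, max_len=600)
        assert len(hits) == 2
        lengths = sorted(h.inner_length for h in hits)
        assert lengths == [150, 150 + 150 + len(f1)]

    def test_length_bounds_validated(self, mix):
        with pytest.raises(ValueError):
            in_silico_pcr(mix, "ACGT" * 100, min_len=400, max_len=300)

@settings(derandomize=True, max_examples=20, deadline=None)
@given(st.text(alphabet="ACGT", min_size=291, max_size=379))
def test_primer_x_primer_template_yields_the_constructed_product(x):
    """fwdF1 + X + revcomp(R6) always amplifies exactly X (primer-free)."""
    from markerkit import load_cel48_mix2

    mix = load_cel48_mix2()
    f1 = next(p for p in mix.forward if p.id == "F1")
    r6 = next(p for p in mix.reverse if p.id == "R6")
    template = f1.text + x + rc(r6.text)
    hits = in_silico_pcr(mix, template, max_mismatch=0)
    assert any(h.amplicon_seq == x and h.strand == "+" for h in hits)


class TestReferenceExtraction:
    def test_exact_substring_recovered(self):
        import random

        rng = random.Random(3)
        gene = "".join(rng.choice("ACGT") for _ in range(1200))
        ref = gene[400:744]
        assert extract_amplicon_by_reference(ref, gene) == ref

    def test_mutated_reference_recovers_region(self):
        import random

        rng = random.Random(4)
        gene = "".join(rng.choice("ACGT") for _ in range(1200))
        region = gene[400:744]
        mutated = list(region)
        for i in rng.sample(range(len(mutated)), int(0.1 * len(mutated))):
            mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
        got = extract_amplicon_by_reference("".join(mutated), gene)
        assert got is not None
        start = gene.find(got)
        assert abs(start - 400) <= 2
        assert abs((start + len(got)) - 744) <= 2

    def test_unrelated_reference_returns_none(self):
        import random

        rng = random.Random(6)
        gene = "".join(rng.choice("ACGT") for _ in range(800))
        ref = "".join(rng.choice("ACGT") for _ in range(344))
        assert extract_amplicon_by_reference(ref, gene, min_identity=90.0) is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            extract_amplicon_by_reference("", "ACGT" * 100)
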