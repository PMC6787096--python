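"""Library design: cross product, half-oligos, assembly, scrambled controls."""

import pytest
from hypothesis import given, strategies as st

from tcgi import (
    CONTROL,
    Category,
    Guide,
    KmerIndex,
    assemble_full_cassette,
    build_cross_library,
    design_half_oligos,
    generate_scrambled_controls,
    load_components,
    revcomp,
)
from tcgi.library import internal_bsmbi_positions


class TestCrossLibrary:
    def test_single_pair(self, toy_guides):
        anchor, _, gene_b, _, _ = toy_guides
        lib = build_cross_library([anchor], [gene_b])
        assert len(lib) == 1
        assert lib[0].id == "anchorA__geneB"
        assert lib[0].category is Category.DOUBLE_KO

    def test_category_partition_hand_enumerated(self, toy_guides):
        anchor, ctrl1, gene_b, gene_c, ctrl2 = toy_guides
        lib = build_cross_library([anchor, ctrl1], [gene_b, gene_c, ctrl2])
        assert len(lib) == 6
        by_cat = {}
        for c in lib:
            by_cat[c.category] = by_cat.get(c.category, 0) + 1
        # anchor x {geneB, geneC} double; anchor x ctrlY single (KO in pos 1);
        # ctrlX x {geneB, geneC} single (KO in pos 2); ctrlX x ctrlY background
        assert by_cat == {
            Category.DOUBLE_KO: 2,
            Category.SINGLE_KO_POS1: 1,
            Category.SINGLE_KO_POS2: 2,
            Category.CTRL_CTRL: 1,
        }

    def test_deterministic_pos1_major_order(self, toy_guides):
        anchor, ctrl1, gene_b, gene_c, ctrl2 = toy_guides
        lib = build_cross_library([anchor, ctrl1], [gene_b, gene_c, ctrl2])
        assert [c.id for c in lib[:3]] == ["anchorA__geneB", "anchorA__geneC", "anchorA__ctrlY"]

    def test_duplicate_id_rejected(self, toy_guides):
        anchor, _, gene_b, _, _ = toy_guides
        dup = Guide("anchorA", "YAP", "ACGTACGTACGTACGTACGA", 1)
        with pytest.raises(ValueError, match="anchorA"):
            build_cross_library([anchor, dup], [gene_b])

    def test_empty_manifest_rejected(self, toy_guides):
        with pytest.raises(ValueError, match="empty"):
            build_cross_library([], [toy_guides[2]])

    def test_wrong_slot_rejected(self, toy_guides):
        anchor, _, gene_b, _, _ = toy_guides
        with pytest.raises(ValueError, match="slot"):
            build_cross_library([gene_b], [anchor])

    @given(n1=st.integers(1, 5), n2=st.integers(1, 7))
    def test_size_law(self, n1, n2):
        pos1 = [Guide(f"a{i}", "TAZ", "A" * 20, 1) for i in range(n1)]
        pos2 = [Guide(f"b{i}", CONTROL if i % 2 else f"G{i}", "C" * 20, 2) for i in range(n2)]
        lib = build_cross_library(pos1, pos2)
        assert len(lib) == n1 * n2
        cats = [c.category for c in lib]
        assert sum(cats.count(c) for c in Category) == len(lib)


class TestHalfOligos:
    def test_lengths_and_assembly(self, components, rng):
        g = Guide("g1", "TAZ", "".join(rng.choice(list("ACGT"), size=20)), 1)
        a, b = design_half_oligos(g, components)
        assert len(a) == 129 and len(b) == 129
        cassette = assemble_full_cassette(a, b, junction=components.junction)
        assert len(cassette) == 227
        # oligo length law
        assert len(a) + len(b) - len(components.junction) == len(cassette)
        # the junction occurs exactly once in the product
        assert cassette.count(components.junction) == 1

    def test_concatenation_matches_independent_oracle(self, components):
        # rebuild both oligos by plain string concatenation of the component
        # sequences, independently of the design code path
        proto = "ATGCATGCATGCATGCATGC"
        g = Guide("g", "TAZ", proto, 1)
        a, b = design_half_oligos(g, components)
        trc, trna = components.trcrna, components.trna
        k = 129 - 20 - 20 - len(trc)
        m = 129 - 20 - 20 - len(trna)
        expected_a = components.bsmbi_adapter_5 + proto + trc + trna[:k]
        expected_b = trc[len(trc) - m :] + trna + proto + components.bsmbi_adapter_3
        assert a == expected_a
        assert b == expected_b
        expected_cassette = (
            components.bsmbi_adapter_5 + proto + trc + trna + proto + components.bsmbi_adapter_3
        )
        assert assemble_full_cassette(a, b, junction=components.junction) == expected_cassette

    def test_amplification_primers_at_termini(self, components):
        g = Guide("g", "TAZ", "ATGCATGCATGCATGCATGC", 1)
        a, b = design_half_oligos(g, components)
        p = components.primers
        assert a.startswith(p["bsmbi_f"])
        assert a.endswith(revcomp(p["trc_trna_r"]))
        assert p["trc_trna_f"] in b[:40]
        assert b.endswith(revcomp(p["bsmbi_r"]))

    def test_bad_protospacer_rejected(self, components):
        with pytest.raises(ValueError):
            Guide("g", "TAZ", "", 1)
        with pytest.raises(ValueError, match="non-DNA"):
            Guide("g", "TAZ", "ATGXATGCATGCATGCATGC", 1)
        short = Guide("g", "TAZ", "ATGC", 1)
        with pytest.raises(ValueError, match="20-nt"):
            design_half_oligos(short, components)

    def test_unreachable_target_length_reports_achieved(self, components):
        from dataclasses import replace

        bad = replace(components, half_oligo_length=100)
        g = Guide("g", "TAZ", "ATGCATGCATGCATGCATGC", 1)
        with pytest.raises(ValueError, match="100"):
            design_half_oligos(g, bad)

    def test_junction_mismatch_rejected(self, components):
        g = Guide("g", "TAZ", "ATGCATGCATGCATGCATGC", 1)
        a, b = design_half_oligos(g, components)
        # one substitution inside the junction region of oligo B
        mutated = b[:10] + ("A" if b[10] != "A" else "C") + b[11:]
        with pytest.raises(ValueError):
            assemble_full_cassette(a, mutated, junction=components.junction)

    def test_overlap_found_without_explicit_junction(self, components):
        g = Guide("g", "TAZ", "ATGCATGCATGCATGCATGC", 1)
        a, b = design_half_oligos(g, components)
        assert len(assemble_full_cassette(a, b)) == 227

    def test_internal_bsmbi_site_flagged(self, components):
        clean = Guide("g", "TAZ", "ATGCATGCATGCATGCATGC", 1)
        a, b = design_half_oligos(clean, components)
        cassette = assemble_full_cassette(a, b, junction=components.junction)
        assert internal_bsmbi_positions(cassette, components) == []
        hot = Guide("g", "TAZ", "ATGCATCGTCTCGCATGCAT", 1)  # carries CGTCTC
        a, b = design_half_oligos(hot, components)
        cassette = assemble_full_cassette(a, b, junction=components.junction)
        assert internal_bsmbi_positions(cassette, components)


class TestScrambledControls:
    def test_empty_request(self):
        assert generate_scrambled_controls(0, seed=1) == []

    def test_absent_from_reference_by_exhaustive_scan(self, rng):
        reference = "".join(rng.choice(list("ACGT"), size=1000))
        index = KmerIndex.from_sequences([reference], k=20)
        controls = generate_scrambled_controls(5, length=20, exclusion_index=index, seed=42)
        assert len(controls) == 5
        assert len({c.protospacer for c in controls}) == 5
        for c in controls:
            assert c.target == CONTROL
            # brute-force substring scan of both strands
            assert c.protospacer not in reference
            assert revcomp(c.protospacer) not in reference

    def test_deterministic_under_seed(self):
        a = generate_scrambled_controls(10, seed=99)
        b = generate_scrambled_controls(10, seed=99)
        assert [g.protospacer for g in a] == [g.protospacer for g in b]
        c = generate_scrambled_controls(10, seed=100)
        assert [g.protospacer for g in a] != [g.protospacer for g in c]

    def test_dense_exclusion_raises_with_attempt_count(self):
        # a reference containing every 2-mer makes length-2 requests impossible
        all_kmers = "".join(a + b for a in "ACGT" for b in "ACGT")
        index = KmerIndex.from_sequences([all_kmers], k=2)
        # also exclude junctions by indexing a shifted copy
        index2 = KmerIndex.from_sequences([all_kmers, all_kmers[1:]], k=2)
        with pytest.raises(RuntimeError, match="draws"):
            generate_scrambled_controls(
                1, length=2, exclusion_index=index2, seed=0, max_attempts_per_guide=200
            )
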