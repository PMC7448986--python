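"""Spliced protein-to-genome alignment and best-model selection."""

import numpy as np
import pytest

from chemoscan.locusbuild import CandidateLocus
from chemoscan.seqs import revcomp, translate
from chemoscan.sixframe import HSP
from chemoscan.splicedmodel import select_best_model, spliced_align

from _oracles import sw_score
from conftest import back_translate, random_dna, random_protein


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


def make_gene(rng, n_codons=200, intron_after=(), intron_len=150):
    prot = "M" + random_protein(rng, n_codons - 1)
    cds = back_translate(prot, rng)
    parts, prev = [], 0
    for c in intron_after:
        parts.append(cds[3 * prev : 3 * c])
        parts.append("GT" + random_dna(rng, intron_len - 4) + "AG")
        prev = c
    parts.append(cds[3 * prev :])
    return prot, cds, "".join(parts)


class TestSplicedAlign:
    def test_intronless_exact_recovery(self, rng):
        prot, cds, gene = make_gene(rng)
        dna = random_dna(rng, 300) + gene + random_dna(rng, 300)
        m = spliced_align(prot, dna, "+")
        assert m.exons == [(300, 300 + len(cds))]
        assert m.protein == prot
        assert m.frameshift_events == 0 and m.internal_stop_count == 0

    def test_single_intron_exact_boundary(self, rng):
        prot, cds, gene = make_gene(rng, intron_after=(100,), intron_len=200)
        dna = random_dna(rng, 300) + gene + random_dna(rng, 300)
        m = spliced_align(prot, dna, "+")
        assert m.exons == [(300, 600), (800, 300 + len(gene))]
        assert m.protein == prot

    def test_minus_strand_recovery(self, rng):
        prot, cds, gene = make_gene(rng, intron_after=(80,))
        dna = random_dna(rng, 200) + gene + random_dna(rng, 200)
        m = spliced_align(prot, revcomp(dna), "-")
        assert m.protein == prot
        assert len(m.exons) == 2

    def test_one_bp_deletion_is_one_frameshift(self, rng):
        prot, cds, gene = make_gene(rng)
        mutated = gene[:120] + gene[121:]
        dna = random_dna(rng, 300) + mutated + random_dna(rng, 300)
        m = spliced_align(prot, dna, "+")
        assert m.frameshift_events == 1
        assert len(m.protein) >= 0.95 * len(prot)

    def test_premature_stop_counted_and_x_translated(self, rng):
        prot, cds, gene = make_gene(rng)
        mutated = gene[:150] + "TAA" + gene[153:]
        dna = random_dna(rng, 300) + mutated + random_dna(rng, 300)
        m = spliced_align(prot, dna, "+")
        assert m.internal_stop_count == 1
        assert m.protein[50] == "X"

    def test_score_equals_sw_on_intronless_perfect_match(self, rng, scoring):
        """Intron machinery adds nothing on an intronless exact match."""
        prot, cds, gene = make_gene(rng, n_codons=120)
        dna = random_dna(rng, 150) + gene + random_dna(rng, 150)
        m = spliced_align(prot, dna, "+")
        oracle = sw_score(prot, translate(dna), scoring.matrix,
                          scoring.gap_open + scoring.gap_extend, scoring.gap_extend)
        assert m.model_score == pytest.approx(oracle)

    def test_all_reported_introns_are_gt_ag(self, rng):
        for k in range(5):
            prot, cds, gene = make_gene(rng, intron_after=(40, 90, 150), intron_len=80)
            dna = random_dna(rng, 200) + gene + random_dna(rng, 200)
            m = spliced_align(prot, dna, "+")
            for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
                assert dna[e1 : e1 + 2] == "GT"
                assert dna[s2 - 2 : s2] == "AG"

    def test_no_alignment_gives_rejected_model(self, rng):
        m = spliced_align("W" * 60, "A" * 400, "+")
        assert m.status == "rejected" and m.exons == []

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError, match="50 aa"):
            spliced_align("MKV", "ACGT" * 100, "+")


def _locus_for(gene_dna, refs_hits, scaffold="s"):
    hsps = [
        HSP(query_id=q, scaffold_id=scaffold, frame=1, query_range=(0, 50),
            subject_range=(0, 150), strand="+", raw_score=sc, bit_score=sc / 2,
            evalue=1e-30)
        for q, sc in refs_hits
    ]
    return CandidateLocus(
        locus_id="L1", scaffold_id=scaffold, strand="+",
        core_range=(0, len(gene_dna)), flanked_range=(0, len(gene_dna)),
        supporting_hsps=hsps, best_query=refs_hits[0][0],
    )


class TestSelectBestModel:
    def test_single_reference_returned(self, rng):
        prot, cds, gene = make_gene(rng)
        dna = random_dna(rng, 100) + gene + random_dna(rng, 100)
        locus = _locus_for(dna, [("r1", 100.0)])
        m = select_best_model(locus, {"r1": prot}, {"s": dna})
        assert m is not None and m.reference_id == "r1"

    def test_true_source_beats_diverged_reference(self, rng):
        from chemoscan.genomeforge import mutate_protein

        prot, cds, gene = make_gene(rng)
        dna = random_dna(rng, 100) + gene + random_dna(rng, 100)
        far = mutate_protein(prot, 0.3, rng)
        locus = _locus_for(dna, [("true", 100.0), ("far", 90.0)])
        m = select_best_model(locus, {"true": prot, "far": far}, {"s": dna})
        assert m.reference_id == "true"

    def test_tie_breaks_to_lexicographic_reference(self, rng):
        prot, cds, gene = make_gene(rng)
        dna = random_dna(rng, 100) + gene + random_dna(rng, 100)
        locus = _locus_for(dna, [("rb", 100.0), ("ra", 100.0)])
        m = select_best_model(locus, {"rb": prot, "ra": prot}, {"s": dna})
        assert m.reference_id == "ra"

    def test_all_rejected_returns_none(self, rng):
        dna = "A" * 600
        locus = _locus_for(dna, [("r1", 10.0)])
        assert select_best_model(locus, {"r1": "W" * 60}, {"s": dna}) is None
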