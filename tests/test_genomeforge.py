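"""Synthetic genome forge: round-trips, determinism, defect construction,
and the shared codon-pair simulator."""

import numpy as np
import pytest

from chemoscan.codonmodel import CodonSimSpec, simulate_codon_pair
from chemoscan.genomeforge import (
    FamilySpec,
    forge_genome,
    forge_transcripts,
    rescue_scenario,
)
from chemoscan.seqs import revcomp, translate


def small_spec(**kw):
    base = dict(
        family_name="OR", n_genes=8, n_pseudo_stop=1, n_pseudo_frameshift=1,
        n_partial=1, tandem_cluster_sizes=(3,), scaffold_count=2,
        scaffold_length=100_000, rng_seed=7,
    )
    base.update(kw)
    return FamilySpec(**base)


def truth_cds_from_genome(genome, rec):
    seq = "".join(genome[rec.scaffold][s:e] for s, e in sorted(rec.exons))
    return revcomp(seq) if rec.strand == "-" else seq


class TestForgeGenome:
    def test_exon_translation_roundtrip(self):
        genome, truth, refs = forge_genome(small_spec())
        for rec in truth:
            assert truth_cds_from_genome(genome, rec) == rec.cds
            if rec.status == "intact":
                assert translate(rec.cds) == rec.protein
                assert "*" not in rec.protein

    def test_single_intronless_gene_embeds_cds_verbatim(self):
        spec = small_spec(n_genes=1, n_pseudo_stop=0, n_pseudo_frameshift=0,
                          n_partial=0, tandem_cluster_sizes=(),
                          intron_count_range=(0, 0), scaffold_count=1)
        genome, truth, refs = forge_genome(spec)
        rec = truth.records[0]
        assert len(rec.exons) == 1
        assert rec.cds in genome[rec.scaffold] or revcomp(rec.cds) in genome[rec.scaffold]

    def test_stop_pseudogene_has_internal_stop(self):
        genome, truth, _ = forge_genome(small_spec())
        (rec,) = truth.by_status("pseudo_stop")
        prot = translate(rec.cds)
        assert "*" in prot[:-1]
        assert rec.protein[prot.index("*")] == "X"

    def test_frameshift_pseudogene_cds_not_multiple_of_3(self):
        genome, truth, _ = forge_genome(small_spec())
        (rec,) = truth.by_status("pseudo_frameshift")
        assert len(rec.cds) % 3 != 0

    def test_tandem_cluster_within_50kb_window(self):
        # with 2 solo intact genes, the 3-gene cluster is g003..g005
        genome, truth, _ = forge_genome(small_spec())
        cluster = [r for r in truth if r.gene_id in ("OR_g003", "OR_g004", "OR_g005")]
        assert len({r.scaffold for r in cluster}) == 1
        assert len({r.strand for r in cluster}) == 1
        lo = min(r.span[0] for r in cluster)
        hi = max(r.span[1] for r in cluster)
        assert hi - lo <= 50_000

    def test_intron_boundaries_are_gt_ag(self):
        genome, truth, _ = forge_genome(small_spec())
        for rec in truth:
            ex = sorted(rec.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                intron = genome[rec.scaffold][e1:s2]
                if rec.strand == "-":
                    intron = revcomp(intron)
                assert intron[:2] == "GT" and intron[-2:] == "AG"

    def test_seed_determinism(self):
        g1, t1, r1 = forge_genome(small_spec())
        g2, t2, r2 = forge_genome(small_spec())
        assert g1 == g2 and r1 == r2
        assert [(x.gene_id, x.exons, x.status) for x in t1] == [
            (x.gene_id, x.exons, x.status) for x in t2
        ]

    def test_refs_differ_from_planted_proteins(self):
        _, truth, refs = forge_genome(small_spec())
        prots = {r.gene_id: r.protein for r in truth.intact()}
        for rec in truth.intact():
            assert refs[f"REF_{rec.gene_id}"] != prots[rec.gene_id]

    def test_oversized_family_raises_sizing_error(self):
        with pytest.raises(ValueError, match="scaffold"):
            forge_genome(small_spec(scaffold_count=1, scaffold_length=20_000))

    def test_defect_counts_cannot_exceed_genes(self):
        with pytest.raises(ValueError, match="exceed"):
            small_spec(n_pseudo_stop=8, n_pseudo_frameshift=8)


class TestForgeTranscripts:
    def test_zero_truncation_gives_exact_cds(self):
        _, truth, _ = forge_genome(small_spec())
        tr = forge_transcripts(truth, seed=1, truncation=(0, 0))
        cds = {f"TR_{r.gene_id}": r.cds for r in truth.intact()}
        assert tr == cds

    def test_extra_genes_have_no_genome_counterpart(self):
        _, truth, _ = forge_genome(small_spec())
        extra = {"EXT1": "M" + "ACDEFGHIKLMNPQRSTVWY" * 15}
        tr = forge_transcripts(truth, extra_genes=extra, seed=1)
        assert len(tr) == len(truth.intact()) + 1
        assert translate(tr["TR_extra_EXT1"]) == extra["EXT1"]

    def test_empty_truth_rejected(self):
        from chemoscan.genomeforge import TruthSet

        with pytest.raises(ValueError):
            forge_transcripts(TruthSet([]), seed=0)


class TestRescueScenario:
    def test_structure(self):
        genome, truth, refs, meta = rescue_scenario(seed=1)
        assert {r.gene_id for r in truth} == {"OR_A", "OR_B"}
        assert list(refs) == ["REF_OR_A"]
        hidden = next(r for r in truth if r.gene_id == meta["hidden_gene"])
        assert len(hidden.exons) == 10  # short-exon architecture


class TestCodonPairSimulator:
    def test_zero_branch_length_identical(self):
        (a, b), cats = simulate_codon_pair(CodonSimSpec(model="M7", n_codons=200, t=0.0))
        assert a == b

    def test_m8_selected_fraction_binomial(self):
        spec = CodonSimSpec(model="M8", n_codons=300, t=0.5, p0=0.5, omega_s=2.0,
                            rng_seed=5)
        _, cats = simulate_codon_pair(spec)
        n_sel = int((cats == 10).sum())
        sd = np.sqrt(300 * 0.5 * 0.5)
        assert abs(n_sel - 150) <= 3 * sd

    def test_m8_with_p0_one_matches_m7_pattern_frequencies(self):
        """With no selected class, M8 output is distributed like M7."""
        n = 10_000
        def diff_fraction(model, p0):
            spec = CodonSimSpec(model=model, n_codons=n, t=0.4, beta_p=0.6,
                                beta_q=1.4, p0=p0, omega_s=2.0, rng_seed=9)
            (a, b), _ = simulate_codon_pair(spec)
            return np.mean([a[i:i+3] != b[i:i+3] for i in range(0, 3 * n, 3)])
        f7 = diff_fraction("M7", 1.0)
        f8 = diff_fraction("M8", 1.0)
        se = np.sqrt(2 * 0.25 / n)
        assert abs(f7 - f8) < 4 * se

    def test_divergence_monotone_in_t(self):
        fracs = []
        for t in (0.05, 0.2, 0.6, 1.5):
            spec = CodonSimSpec(model="M7", n_codons=10_000, t=t, rng_seed=3)
            (a, b), _ = simulate_codon_pair(spec)
            fracs.append(np.mean([a[i:i+3] != b[i:i+3] for i in range(0, len(a), 3)]))
        assert fracs == sorted(fracs)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CodonSimSpec(model="M8", omega_s=0.5)
        with pytest.raises(ValueError):
            CodonSimSpec(p0=1.5)
        with pytest.raises(ValueError):
            CodonSimSpec(t=-1.0)
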