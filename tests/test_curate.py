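"""Retention/pseudogene/family rules, two-round orchestration, and the
transcript completeness check."""

import numpy as np
import pytest

from chemoscan.config import PipelineConfig
from chemoscan.curate import (
    AnnotationSet,
    FamilyDb,
    assign_family,
    classify_status,
    completeness_check,
    run_two_round,
)
from chemoscan.genomeforge import (
    forge_decoys,
    forge_genome,
    forge_transcripts,
    mutate_protein,
    rescue_scenario,
)
from chemoscan.pipeline import evaluate_against_truth
from chemoscan.splicedmodel import GeneModel

from conftest import back_translate, random_protein


def model_of(protein, stops=0, fs=0, **kw):
    base = dict(
        gene_id="g", locus_id="l", scaffold_id="s", strand="+",
        exons=[(0, 3 * len(protein))], cds="", protein=protein,
        model_score=100.0, frameshift_events=fs, internal_stop_count=stops,
        reference_id="r",
    )
    base.update(kw)
    return GeneModel(**base)


class TestClassifyStatus:
    def test_half_length_rule_rejects(self):
        # 195 aa clean model against a 400 aa reference: below half length
        assert classify_status(model_of("A" * 195), 400) == "rejected"

    def test_190_aa_floor_rejects(self):
        # 189 aa model passes half of a 300 aa reference but not the size floor
        assert classify_status(model_of("A" * 189), 300) == "rejected"

    def test_exactly_191_aa_retained_as_partial(self):
        assert classify_status(model_of("A" * 191), 300) == "partial"

    def test_pseudogene_exempt_from_length_filters(self):
        assert classify_status(model_of("A" * 120 + "X" * 5, stops=1), 400) == "pseudogene"
        assert classify_status(model_of("A" * 250, fs=1), 400) == "pseudogene"

    def test_full_length_at_ninety_percent(self):
        assert classify_status(model_of("A" * 360), 400) == "full"
        assert classify_status(model_of("A" * 359), 400) == "partial"


class TestAssignFamily:
    @pytest.fixture(scope="class")
    def db(self):
        rng = np.random.default_rng(1)
        ors = {f"OR{i}": random_protein(rng, 400) for i in range(3)}
        grs = {f"GR{i}": random_protein(rng, 400) for i in range(3)}
        decoys = forge_decoys(3, seed=5)
        return FamilyDb({"OR": ors, "GR": grs}, decoys=decoys), ors, decoys

    def test_identical_to_reference(self, db):
        fdb, ors, _ = db
        assert assign_family(ors["OR1"], fdb) == "OR"

    def test_decoy_best_hit_is_inconsistent(self, db):
        fdb, _, decoys = db
        assert assign_family(decoys["DECOY_01"], fdb) == "inconsistent"

    def test_small_margin_is_inconsistent(self, db):
        fdb, ors, _ = db
        rng = np.random.default_rng(2)
        # a protein equally far from OR and GR references: random sequence
        # that hits no family convincingly still needs a decoy-free call
        chimera = ors["OR0"][:200] + fdb.entries[3][2][:200]  # OR half + GR half
        assert assign_family(chimera, fdb, margin_bits=500.0) == "inconsistent"

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            FamilyDb({})


class TestTwoRounds:
    def test_empty_genome_empty_annotation(self, scoring):
        rng = np.random.default_rng(0)
        genome = {"s": "".join(rng.choice(list("ACGT"), 50_000))}
        refs = {"R1": random_protein(rng, 400)}
        ann = run_two_round(genome, refs, PipelineConfig(), family="OR")
        assert ann.counts == (0, 0, 0, 0)
        assert ann.round1.counts == (0, 0, 0, 0)

    def test_fixed_point_when_refs_complete(self, small_forge):
        _, genome, truth, refs = small_forge
        ann = run_two_round(genome, refs, PipelineConfig(), family="OR")
        assert len(ann.models) >= len(ann.round1.models)  # monotone
        assert len(ann.models) == len(ann.round1.models)  # and a fixed point here

    def test_counts_conserved(self, small_forge):
        _, genome, truth, refs = small_forge
        ann = run_two_round(genome, refs, PipelineConfig(), family="OR")
        total, full, part, pseudo = ann.counts
        assert total == full + part + pseudo == len(ann.models)

    def test_round2_rescues_short_exon_paralog(self):
        """A gene whose only reference support is a distant paralog
        reference becomes annotatable once round 1's protein joins the
        query set."""
        genome, truth, refs, meta = rescue_scenario(seed=1)
        ann = run_two_round(genome, refs, PipelineConfig(), family="OR")
        hidden = next(r for r in truth if r.gene_id == meta["hidden_gene"])

        def covered(annset):
            for m in annset.models:
                span = (min(s for s, _ in m.exons), max(e for _, e in m.exons))
                ov = max(0, min(span[1], hidden.span[1]) - max(span[0], hidden.span[0]))
                if m.scaffold_id == hidden.scaffold and ov > 0.5 * (hidden.span[1] - hidden.span[0]):
                    return True
            return False

        assert not covered(ann.round1)
        assert covered(ann)

    def test_no_decoy_ever_annotated(self, small_forge):
        _, genome, truth, refs = small_forge
        cfg = PipelineConfig()
        db = FamilyDb({"OR": refs}, decoys=forge_decoys(8, seed=3), scoring=cfg.scoring)
        ann = run_two_round(genome, refs, cfg, family="OR", db=db)
        rep = evaluate_against_truth(ann, truth)
        assert rep.precision == 1.0


class TestCompleteness:
    @pytest.fixture(scope="class")
    def annotated(self, small_forge):
        _, genome, truth, refs = small_forge
        ann = run_two_round(genome, refs, PipelineConfig(), family="OR")
        return truth, refs, ann

    def test_three_absent_genes_reported_missing(self, annotated):
        truth, refs, ann = annotated
        rng = np.random.default_rng(4)
        extras = {f"ABS{i}": mutate_protein(refs[list(refs)[i]], 0.1, rng) for i in range(3)}
        tr = forge_transcripts(truth, extra_genes=extras, seed=2)
        rep = completeness_check(tr, refs, ann)
        assert rep.transcripts_missing == 3
        assert rep.transcripts_total == len(truth.intact()) + 3
        assert rep.transcripts_found_in_annotation + rep.transcripts_missing == rep.transcripts_total

    def test_threshold_boundaries_119_120(self, annotated):
        """A transcript with exactly 119 homologous aa is not counted; 120 is."""
        truth, refs, ann = annotated
        rng = np.random.default_rng(5)
        rid = list(refs)[0]
        t119 = back_translate(refs[rid][:119], rng)
        t120 = back_translate(refs[rid][:120], rng)
        r119 = completeness_check({"t": t119}, refs, ann, threshold_aa=120)
        r120 = completeness_check({"t": t120}, refs, ann, threshold_aa=120)
        assert r119.transcripts_total == 0
        assert r120.transcripts_total == 1

    def test_threshold_boundaries_189_190(self, annotated):
        truth, refs, ann = annotated
        rng = np.random.default_rng(6)
        rid = list(refs)[1]
        r189 = completeness_check({"t": back_translate(refs[rid][:189], rng)}, refs, ann,
                                  threshold_aa=190)
        r190 = completeness_check({"t": back_translate(refs[rid][:190], rng)}, refs, ann,
                                  threshold_aa=190)
        assert r189.transcripts_total == 0
        assert r190.transcripts_total == 1
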