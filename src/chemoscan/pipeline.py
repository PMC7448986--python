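"""End-to-end orchestration and truth-based evaluation.

``run_pipeline`` executes the stages in protocol order — two-round
annotation per species and family, transcript completeness, family
tree with bootstraps, orthologue pairing between the two species, and
the M7-vs-M8 selection test per pair — writing every stage's outputs
into a run directory with a structured log and a config-hash manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .config import PipelineConfig
from .curate import AnnotationSet, FamilyDb, completeness_check, run_two_round
from .genomeforge import TruthSet
from .phylo import PhyloTree, build_msa, build_tree, filter_for_tree, find_ortholog_pairs
from .sitesel import analyze_pair, codon_align
from .sixframe import GenomeIndex

log = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    name: str
    genome: dict[str, str]
    transcripts: dict[str, str] | None = None


@dataclass
class RunResult:
    annotations: dict = field(default_factory=dict)  # (species, family) -> AnnotationSet
    completeness: dict = field(default_factory=dict)  # (species, family) -> report
    trees: dict = field(default_factory=dict)  # family -> PhyloTree
    pairs: dict = field(default_factory=dict)  # family -> [OrthologPair]
    selection: dict = field(default_factory=dict)  # family -> [SelectionResult]


def run_pipeline(
    config: PipelineConfig,
    species_inputs: list[SpeciesInput],
    family_refs: dict[str, dict[str, str]],
    decoys: dict[str, str] | None = None,
    outdir: str | Path | None = None,
    outgroups: dict[str, list[str]] | None = None,
    selection_restarts: int = 2,
) -> RunResult:
    """Run annotation (+ completeness) per species, then, when exactly
    two species are given, tree/pairs/selection per family."""
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        cio.write_manifest(config.to_dict(), out / "manifest.json")
    db = FamilyDb(family_refs, decoys=decoys, scoring=config.scoring)
    result = RunResult()

    for sp in species_inputs:
        index = GenomeIndex(sp.genome)
        for family, refs in family_refs.items():
            log.info("annotating %s / %s (%d references)", sp.name, family, len(refs))
            ann = run_two_round(
                sp.genome, refs, config, family=family, db=db, species=sp.name, index=index
            )
            result.annotations[(sp.name, family)] = ann
            log.info("%s/%s: total=%d full=%d partial=%d pseudo=%d",
                     sp.name, family, *ann.counts)
            if out:
                cio.write_models_gff3(ann.models, out / f"{sp.name}_{family}.gff3")
                cio.write_fasta(ann.proteins(), out / f"{sp.name}_{family}_proteins.fa")
                cio.write_fasta({m.gene_id: m.cds for m in ann.models},
                                out / f"{sp.name}_{family}_cds.fa")
            if sp.transcripts is not None:
                rep = completeness_check(sp.transcripts, refs, ann, config=config)
                result.completeness[(sp.name, family)] = rep
                log.info("%s/%s completeness: %d/%d found", sp.name, family,
                         rep.transcripts_found_in_annotation, rep.transcripts_total)
            else:
                log.info("%s/%s: no transcripts provided; completeness stage skipped",
                         sp.name, family)
        if out:
            cio.write_counts_tsv(
                [a for (s, _f), a in result.annotations.items() if s == sp.name],
                out / f"{sp.name}_counts.tsv",
            )

    if len(species_inputs) == 2:
        sp_a, sp_b = (s.name for s in species_inputs)
        for family in family_refs:
            ann_a = result.annotations[(sp_a, family)]
            ann_b = result.annotations[(sp_b, family)]
            proteins = {}
            species_map = {}
            models_by_id = {}
            for ann, sp in ((ann_a, sp_a), (ann_b, sp_b)):
                for m in ann.models:
                    if "X" in m.protein:  # pseudogenes stay out of the tree
                        continue
                    proteins[m.gene_id] = m.protein
                    species_map[m.gene_id] = sp
                    models_by_id[m.gene_id] = m
            og = outgroups.get(family, []) if outgroups else []
            for o in og:
                proteins[o] = family_refs[family][o] if o in family_refs[family] else proteins[o]
                species_map[o] = "outgroup"
            proteins = filter_for_tree(proteins, family)
            if len(proteins) < 4:
                log.warning("family %s: <4 sequences after tree filters; skipping tree", family)
                continue
            msa = build_msa(proteins)
            tree = build_tree(
                msa, family, n_bootstrap=config.n_bootstrap, seed=config.rng_seed,
                outgroup=[o for o in og if o in proteins], midpoint_fallback=True,
            )
            result.trees[family] = tree
            pairs = find_ortholog_pairs(tree, species_map, focal=(sp_a, sp_b))
            result.pairs[family] = pairs
            log.info("family %s: %d orthologue pairs", family, len(pairs))
            if out:
                (out / f"{family}_tree.nwk").write_text(tree.newick())
                cio.write_pairs_tsv(pairs, out / f"{family}_pairs.tsv")

            sel = []
            for k, pr in enumerate(pairs):
                ma, mb = models_by_id[pr.gene_a], models_by_id[pr.gene_b]
                pair_msa = build_msa({pr.gene_a: ma.protein, pr.gene_b: mb.protein})
                aln = codon_align(
                    (pair_msa.row(pr.gene_a), pair_msa.row(pr.gene_b)),
                    ma.cds, mb.cds, ids=(pr.gene_a, pr.gene_b),
                )
                if aln.n_codons < 30:
                    log.warning("pair %s-%s: alignment below 30 codons; skipped",
                                pr.gene_a, pr.gene_b)
                    continue
                res = analyze_pair(
                    aln, pair_id=f"{pr.gene_a}|{pr.gene_b}",
                    n_restarts=selection_restarts, seed=config.rng_seed + k,
                    alpha=config.lrt_alpha, posterior_cutoff=config.posterior_cutoff,
                    df=config.df,
                )
                sel.append(res)
            result.selection[family] = sel
            if out:
                cio.write_selection_tsv(sel, out / f"{family}_selection.tsv")
    return result


# ----------------------------------------------------------------- evaluate


@dataclass
class EvaluationReport:
    n_truth: int
    n_models: int
    sensitivity: float
    intact_sensitivity: float
    precision: float | None  # None = NA (no models)
    pseudogene_status_accuracy: float | None
    status_confusion: dict = field(default_factory=dict)


def _exon_union(intervals) -> list[tuple[int, int]]:
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _union_len(intervals) -> int:
    return sum(e - s for s, e in intervals)


def _overlap_len(a, b) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def evaluate_against_truth(models, truth: TruthSet, min_reciprocal: float = 0.5) -> EvaluationReport:
    """Gene-level comparison: a model matches a truth gene when their
    exon unions overlap reciprocally by at least ``min_reciprocal``."""
    if isinstance(models, AnnotationSet):
        models = models.models
    truth_status = {"intact": "full_or_partial", "partial": "full_or_partial",
                    "pseudo_stop": "pseudogene", "pseudo_frameshift": "pseudogene"}
    matches = {}  # truth gene_id -> model
    used = set()
    for rec in truth:
        t_ex = _exon_union(rec.exons)
        t_len = _union_len(t_ex)
        for m in models:
            if m.gene_id in used or m.scaffold_id != rec.scaffold or m.strand != rec.strand:
                continue
            m_ex = _exon_union(m.exons)
            ov = _overlap_len(t_ex, m_ex)
            if ov >= min_reciprocal * t_len and ov >= min_reciprocal * _union_len(m_ex):
                matches[rec.gene_id] = m
                used.add(m.gene_id)
                break
    n_truth = len(truth)
    n_models = len(models)
    sens = len(matches) / n_truth if n_truth else 0.0
    intact = truth.intact()
    intact_found = sum(1 for r in intact if r.gene_id in matches)
    intact_sens = intact_found / len(intact) if intact else 0.0
    precision = (len(used) / n_models) if n_models else None
    confusion = {}
    pseudo_total = pseudo_ok = 0
    for rec in truth:
        m = matches.get(rec.gene_id)
        called = m.status if m else "missed"
        confusion[(rec.status, called)] = confusion.get((rec.status, called), 0) + 1
        if rec.status in ("pseudo_stop", "pseudo_frameshift"):
            pseudo_total += 1
            pseudo_ok += int(m is not None and m.status == "pseudogene")
    return EvaluationReport(
        n_truth=n_truth,
        n_models=n_models,
        sensitivity=sens,
        intact_sensitivity=intact_sens,
        precision=precision,
        pseudogene_status_accuracy=(pseudo_ok / pseudo_total) if pseudo_total else None,
        status_confusion=confusion,
    )
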