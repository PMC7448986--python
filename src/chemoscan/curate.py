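"""Retention, pseudogene and family-consistency rules; two-round
identification; transcript-based completeness accounting.

Status rules follow the annotation protocol exactly: any model with a
premature stop or a frameshift is a pseudogene (kept, exempt from length
filters); clean models are retained as full length when they cover at
least ``full_length_fraction`` of their reference, or as partial when
they reach at least half the reference length *and* are larger than 190
amino acids; anything shorter is rejected. Candidates whose best
database hit is outside their nominal family (or within less than a
5-bit margin of another family) are removed as inconsistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import PipelineConfig
from .genomeforge import TruthSet  # noqa: F401  (typing convenience for callers)
from .locusbuild import add_flanks, chain_hits, merge_rounds
from .seqs import translate, revcomp
from .sixframe import GenomeIndex, ScoringScheme, search_many
from .splicedmodel import GeneModel, select_best_model

log = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    species: str
    family: str
    models: list[GeneModel] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(total, full_length, partial, pseudogene)."""
        full = sum(1 for m in self.models if m.status == "full")
        part = sum(1 for m in self.models if m.status == "partial")
        pseudo = sum(1 for m in self.models if m.status == "pseudogene")
        return len(self.models), full, part, pseudo

    def proteins(self) -> dict[str, str]:
        return {m.gene_id: m.protein for m in self.models}


@dataclass
class CompletenessReport:
    family: str
    transcripts_total: int
    transcripts_found_in_annotation: int
    transcripts_missing: int
    min_homology_aa: int

    def __post_init__(self):
        assert (
            self.transcripts_found_in_annotation + self.transcripts_missing
            == self.transcripts_total
        )


def classify_status(model: GeneModel, reference_length: int, config: PipelineConfig | None = None) -> str:
    """Status of one gene model given the length of its reference protein.

    Pseudogenes (any stop/frameshift) bypass the length filters; clean
    models must reach 90% of the reference to count as full length, and
    incomplete ones are retained only if they reach at least half the
    reference length and are larger than 190 aa.
    """
    if config is None:
        config = PipelineConfig()
    if model.internal_stop_count >= 1 or model.frameshift_events >= 1:
        return "pseudogene"
    n = len(model.protein)
    if n >= config.full_length_fraction * reference_length:
        return "full"
    if n >= max(config.half_length_fraction * reference_length, config.min_partial_aa + 1):
        return "partial"
    return "rejected"


def _kmer_set(seq: str, k: int = 4) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


class FamilyDb:
    """Labeled reference proteins (families + decoys) for consistency checks."""

    def __init__(self, families: dict[str, dict[str, str]], decoys: dict[str, str] | None = None,
                 scoring: ScoringScheme | None = None):
        if not families or not any(families.values()):
            raise ValueError("family reference database is empty")
        self.scoring = scoring or ScoringScheme()
        self.entries = []  # (label, seq_id, seq, kmers)
        for fam, seqs in families.items():
            for sid, seq in seqs.items():
                self.entries.append((fam, sid, seq, _kmer_set(seq)))
        for sid, seq in (decoys or {}).items():
            self.entries.append(("__decoy__", sid, seq, _kmer_set(seq)))
        self._aligner = self.scoring.aligner()

    def best_hits(self, protein: str, prescreen: int = 12) -> dict[str, float]:
        """Best SW bit score per label, aligning only k-mer-prescreened entries."""
        qk = _kmer_set(protein)
        ranked = sorted(self.entries, key=lambda e: -len(qk & e[3]))
        cand = ranked[:prescreen]
        # ensure every label retains its own best k-mer candidate
        seen = {e[0] for e in cand}
        for e in ranked[prescreen:]:
            if e[0] not in seen:
                cand.append(e)
                seen.add(e[0])
        best: dict[str, float] = {}
        for label, _sid, seq, _k in cand:
            score = self._aligner.align(protein, seq).score
            bits = self.scoring.bit_score(score)
            if bits > best.get(label, float("-inf")):
                best[label] = bits
        return best


def assign_family(protein: str, db: FamilyDb, margin_bits: float = 5.0) -> str:
    """Family of the best database hit, or "inconsistent".

    A candidate is inconsistent when its best hit is a decoy or when the
    winning family leads the runner-up family by less than ``margin_bits``.
    """
    hits = db.best_hits(protein)
    order = sorted(hits, key=lambda l: -hits[l])
    top = order[0]
    if top == "__decoy__":
        return "inconsistent"
    others = [hits[l] for l in order[1:] if l != "__decoy__"]
    if others and hits[top] - max(others) < margin_bits:
        return "inconsistent"
    return top


def dedup_models(models: list[GeneModel]) -> list[GeneModel]:
    """Keep only the best-scoring model among overlapping gene spans.

    Two loci occasionally reconstruct the same gene (e.g. an exon chain
    split by a weak internal exon); only the best model is retained.
    """
    def span(m):
        lo = min(s for s, _ in m.exons)
        hi = max(e for _, e in m.exons)
        return lo, hi

    kept: list[GeneModel] = []
    for m in sorted(models, key=lambda x: -x.model_score):
        s = span(m)
        clash = False
        for other in kept:
            if other.scaffold_id != m.scaffold_id or other.strand != m.strand:
                continue
            o = span(other)
            ov = max(0, min(s[1], o[1]) - max(s[0], o[0]))
            if ov > 0.3 * min(s[1] - s[0], o[1] - o[0]):
                clash = True
                break
        if not clash:
            kept.append(m)
    kept.sort(key=lambda m: (m.scaffold_id, m.exons[0][0]))
    return kept


def _annotate_once(
    index: GenomeIndex,
    genome: dict[str, str],
    queries: dict[str, str],
    reference_pool: dict[str, str],
    config: PipelineConfig,
    prior_hsps=None,
    prior_loci=None,
):
    """One identification round: search -> chain -> flank -> model."""
    hsps = search_many(queries, index, config.scoring, evalue_cutoff=config.evalue_cutoff)
    if prior_hsps:
        hsps = prior_hsps + hsps
    loci = chain_hits(hsps, max_intron=config.max_intron, max_locus_span=config.max_locus_span)
    if prior_loci is not None:
        loci = merge_rounds(prior_loci, loci)
    loci = [add_flanks(l, len(genome[l.scaffold_id]), config.flank_bp) for l in loci]
    models = []
    for locus in loci:
        m = select_best_model(
            locus,
            reference_pool,
            genome,
            top_n=config.top_n_references,
            scoring=config.scoring,
            params=config.spliced,
        )
        if m is not None:
            models.append(m)
    return hsps, loci, models


def _curate_models(models, reference_pool, family, db: FamilyDb, config) -> list[GeneModel]:
    retained = []
    for m in models:
        ref_len = m.reference_length or len(reference_pool.get(m.reference_id, ""))
        status = classify_status(m, ref_len, config)
        if status == "rejected":
            log.info("model %s rejected by length filters (%d aa vs ref %d)",
                     m.gene_id, len(m.protein), ref_len)
            continue
        fam = assign_family(m.protein, db, config.family_margin_bits)
        if fam != family:
            log.info("model %s removed: family annotation %r inconsistent with %s",
                     m.gene_id, fam, family)
            continue
        m.status = status
        m.family = family
        retained.append(m)
    return dedup_models(retained)


def run_two_round(
    genome: dict[str, str],
    family_refs: dict[str, str],
    config: PipelineConfig | None = None,
    family: str = "OR",
    db: FamilyDb | None = None,
    species: str = "speciesA",
    index: GenomeIndex | None = None,
) -> AnnotationSet:
    """Two-round identification of one family in one genome.

    Round 1 searches the external references; round 2 adds the round-1
    retained proteins as queries (and as modelling references), merges
    loci across rounds and re-curates. The returned AnnotationSet has a
    ``round1`` attribute holding the intermediate annotation.
    """
    if config is None:
        config = PipelineConfig()
    if db is None:
        db = FamilyDb({family: family_refs}, scoring=config.scoring)
    if index is None:
        index = GenomeIndex(genome)

    hsps1, loci1, models1 = _annotate_once(index, genome, family_refs, family_refs, config)
    retained1 = _curate_models(models1, family_refs, family, db, config)
    round1 = AnnotationSet(species=species, family=family, models=retained1)
    for i, m in enumerate(round1.models):
        m.gene_id = f"{species}_{family}{i + 1:03d}"

    new_queries = {f"r1_{m.gene_id}": m.protein for m in retained1 if len(m.protein) >= 50}
    pool = dict(family_refs)
    pool.update(new_queries)
    _hsps2, _loci2, models2 = _annotate_once(
        index, genome, new_queries, pool, config, prior_hsps=hsps1, prior_loci=loci1
    )
    retained2 = _curate_models(models2, pool, family, db, config)
    final = AnnotationSet(species=species, family=family, models=retained2)
    for i, m in enumerate(final.models):
        m.gene_id = f"{species}_{family}{i + 1:03d}"
    final.round1 = round1
    return final


def _six_frames(seq: str) -> list[str]:
    rc = revcomp(seq)
    return [translate(seq[i:]) for i in range(3)] + [translate(rc[i:]) for i in range(3)]


def _aligned_stats(aligner, a: str, b: str):
    """(aligned residue-pair columns, identical columns) of the best local alignment."""
    alns = aligner.align(a, b)
    if alns.score <= 0:
        return 0, 0
    aln = alns[0]
    s1, s2 = str(aln[0]), str(aln[1])
    pairs = sum(1 for x, y in zip(s1, s2) if x != "-" and y != "-")
    ident = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return pairs, ident


def completeness_check(
    transcripts: dict[str, str],
    family_refs: dict[str, str],
    annotation: AnnotationSet,
    threshold_aa: int | None = None,
    config: PipelineConfig | None = None,
) -> CompletenessReport:
    """Count family transcripts and how many the annotation accounts for.

    A transcript is a family candidate iff its best translated alignment
    to a family reference spans at least the family threshold (120 aa
    for ORs/GRs, 190 aa for IRs); a candidate is found in the annotation
    iff it aligns to an annotated protein of the family at >= 90%
    identity over at least the threshold.
    """
    if config is None:
        config = PipelineConfig()
    family = annotation.family
    if threshold_aa is None:
        threshold_aa = config.completeness_aa.get(family, 120)
    aligner = config.scoring.aligner()
    ref_k = {rid: _kmer_set(seq) for rid, seq in family_refs.items()}
    ann = annotation.proteins()
    ann_k = {gid: _kmer_set(seq) for gid, seq in ann.items()}

    total = found = 0
    for _tid, seq in sorted(transcripts.items()):
        frames = [f for f in _six_frames(seq) if len(f) >= 20]
        best_span = 0
        for fr in frames:
            fk = _kmer_set(fr)
            for rid in sorted(ref_k, key=lambda r: -len(fk & ref_k[r]))[:4]:
                pairs, _ = _aligned_stats(aligner, fr, family_refs[rid])
                best_span = max(best_span, pairs)
            if best_span >= threshold_aa:
                break
        if best_span < threshold_aa:
            continue
        total += 1
        hit = False
        for fr in frames:
            fk = _kmer_set(fr)
            for gid in sorted(ann_k, key=lambda g: -len(fk & ann_k[g]))[:4]:
                pairs, ident = _aligned_stats(aligner, fr, ann[gid])
                if pairs >= threshold_aa and ident >= config.completeness_identity * pairs:
                    hit = True
                    break
            if hit:
                break
        if hit:
            found += 1
    return CompletenessReport(
        family=family,
        transcripts_total=total,
        transcripts_found_in_annotation=found,
        transcripts_missing=total - found,
        min_homology_aa=threshold_aa,
    )
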