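"""Spliced gene-model construction inside candidate loci.

A reference protein is aligned to the flanked locus DNA by a local DP
with codon-match, codon-indel, frameshift, stop and intron states (see
``_spliced_dp``). The highest-scoring path defines the exon structure,
CDS and translated protein of the gene model; premature stops appear as
X in the protein and are counted, as are frameshift events. Only
canonical GT..AG introns are modelled.

Absolute model scores are implementation-defined alignment units; only
their ranking is meaningful (the best-scoring model per locus is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _spliced_dp as dp
from .locusbuild import CandidateLocus
from .seqs import CODON_TABLE, revcomp
from .sixframe import ScoringScheme

log = logging.getLogger(__name__)


@dataclass
class SplicedParams:
    """Scoring of the spliced aligner (alignment-score units).

    One frameshift outweighs any single mismatch but not model rejection;
    introns are cheap so true splits are preferred over forced indels.
    """

    frameshift_penalty: float = -20.0
    intron_penalty: float = -10.0
    stop_score: float = -15.0
    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_intron: int = 30


@dataclass
class GeneModel:
    gene_id: str
    locus_id: str
    scaffold_id: str
    strand: str
    exons: list[tuple[int, int]]  # forward-strand bp intervals, coding order
    cds: str
    protein: str
    model_score: float
    frameshift_events: int
    internal_stop_count: int
    reference_id: str
    family: str = ""
    status: str = "full"
    reference_length: int = 0

    @property
    def rejected(self) -> bool:
        return self.status == "rejected"


_MATRIX_CACHE: dict[int, tuple] = {}


def _matrix_arrays(scoring: ScoringScheme):
    key = id(scoring.matrix)
    if key not in _MATRIX_CACHE:
        alpha = scoring.matrix.alphabet
        sub = np.array(scoring.matrix, dtype=np.float32)
        aa_to_idx = {a: i for i, a in enumerate(alpha)}
        _MATRIX_CACHE[key] = (sub, aa_to_idx)
    return _MATRIX_CACHE[key]


def _prepare(reference: str, dna: str, scoring: ScoringScheme, params: SplicedParams):
    sub, aa_to_idx = _matrix_arrays(scoring)
    x_idx = aa_to_idx["X"]
    m, n = len(reference), len(dna)
    p_idx = np.array([aa_to_idx.get(a, x_idx) for a in reference], dtype=np.int64)
    codon_idx = np.zeros(n + 1, dtype=np.int64)  # aa-matrix column of codon ending at j
    is_stop = np.zeros(n + 1, dtype=bool)
    for j in range(3, n + 1):
        aa = CODON_TABLE.get(dna[j - 3 : j], "X")
        if aa == "*":
            is_stop[j] = True
            codon_idx[j] = x_idx
        else:
            codon_idx[j] = aa_to_idx.get(aa, x_idx)
    sub_of = np.zeros((m + 1, n + 1), dtype=np.float32)
    if m and n >= 3:
        block = sub[np.ix_(p_idx, codon_idx[3:])]
        block[:, is_stop[3:]] = np.float32(params.stop_score)
        sub_of[1:, 3:] = block
    is_gt = np.zeros(n + 1, dtype=bool)
    is_ag_end = np.zeros(n + 1, dtype=bool)
    for j in range(n - 1):
        if dna[j] == "G" and dna[j + 1] == "T":
            is_gt[j] = True
    for j in range(2, n + 1):
        if dna[j - 2] == "A" and dna[j - 1] == "G":
            is_ag_end[j] = True
    return sub_of, is_gt, is_ag_end


def _traceback(dna, best_i, best_j, tbM, tbIx, tbIy, donor_ptr):
    """Recover exon intervals (coding coords), CDS, protein and defect counts."""
    i, j, state = best_i, best_j, "M"
    steps = []  # (kind, j_start, j_end) in coding coordinates
    while True:
        if state == "M":
            ptr = tbM[i, j]
            if ptr == dp.M_NONE:
                break
            if ptr in (dp.M_START, dp.M_FROM_M, dp.M_FROM_IX, dp.M_FROM_IY):
                steps.append(("codon", j - 3, j))
                i -= 1
                jn = j - 3
                if ptr == dp.M_START:
                    j = jn
                    break
                state = {dp.M_FROM_M: "M", dp.M_FROM_IX: "Ix", dp.M_FROM_IY: "Iy"}[ptr]
                j = jn
            elif ptr == dp.M_FS2:
                steps.append(("fs2", j - 2, j))
                i -= 1
                j -= 2
            elif ptr == dp.M_FS1:
                steps.append(("fs1", j - 1, j))
                j -= 1
            elif ptr == dp.M_INTRON:
                d = int(donor_ptr[i, j])
                steps.append(("intron", d, j))
                j = d
        elif state == "Ix":
            ptr = tbIx[i, j]
            steps.append(("codon_ins", j - 3, j))
            j -= 3
            state = "M" if ptr == 0 else "Ix"
        else:  # Iy
            ptr = tbIy[i, j]
            i -= 1
            state = "M" if ptr == 0 else "Iy"
    steps.reverse()

    exons = []
    cds_parts = []
    protein = []
    frameshifts = 0
    stops = 0
    exon_start = None
    last_fs = False
    pos = None
    for kind, a, b in steps:
        if kind == "intron":
            if exon_start is not None:
                exons.append((exon_start, a))
            exon_start = b
            pos = b
            last_fs = False
            continue
        if exon_start is None:
            exon_start = a
        pos = b
        seg = dna[a:b]
        cds_parts.append(seg)
        if kind == "codon" or kind == "codon_ins":
            aa = CODON_TABLE.get(seg, "X")
            if aa == "*":
                stops += 1
                aa = "X"
            protein.append(aa)
            last_fs = False
        elif kind == "fs2":
            protein.append("X")
            frameshifts += 1
            last_fs = False
        elif kind == "fs1":
            if not last_fs:
                frameshifts += 1
            last_fs = True
    if exon_start is not None and pos is not None and pos > exon_start:
        exons.append((exon_start, pos))
    return exons, "".join(cds_parts), "".join(protein), frameshifts, stops


def spliced_align(
    reference: str,
    locus_dna: str,
    strand: str,
    scoring: ScoringScheme | None = None,
    params: SplicedParams | None = None,
    origin: int = 0,
    scaffold_id: str = "seq",
    locus_id: str = "locus",
    reference_id: str = "ref",
) -> GeneModel:
    """Align ``reference`` to ``locus_dna`` (forward-strand slice) on ``strand``.

    ``origin`` is the forward-strand offset of ``locus_dna`` on its
    scaffold, used to report exon coordinates in scaffold space.
    """
    if scoring is None:
        scoring = ScoringScheme()
    if params is None:
        params = SplicedParams()
    if len(reference) < 50:
        raise ValueError("reference must be at least 50 aa")
    reference = reference.upper().rstrip("*")
    dna = locus_dna.upper()
    work = revcomp(dna) if strand == "-" else dna
    n, m = len(work), len(reference)
    sub_of, is_gt, is_ag_end = _prepare(reference, work, scoring, params)
    score, bi, bj, tbM, tbIx, tbIy, donor_ptr = dp.fill(
        n,
        m,
        sub_of,
        is_gt,
        is_ag_end,
        np.float32(params.gap_open + params.gap_extend),
        np.float32(params.gap_extend),
        np.float32(params.frameshift_penalty),
        np.float32(params.intron_penalty),
        params.min_intron,
    )
    if score <= 0:
        return GeneModel(
            gene_id=f"{locus_id}.g",
            locus_id=locus_id,
            scaffold_id=scaffold_id,
            strand=strand,
            exons=[],
            cds="",
            protein="",
            model_score=float(score),
            frameshift_events=0,
            internal_stop_count=0,
            reference_id=reference_id,
            status="rejected",
            reference_length=m,
        )
    exons_c, cds, protein, fs, stops = _traceback(work, bi, bj, tbM, tbIx, tbIy, donor_ptr)
    # map coding coordinates to forward-strand scaffold coordinates
    exons = []
    for cs, ce in exons_c:
        if strand == "+":
            exons.append((origin + cs, origin + ce))
        else:
            exons.append((origin + n - ce, origin + n - cs))
    for k in range(len(exons_c) - 1):  # splice validity: introns are GT..AG
        d, a = exons_c[k][1], exons_c[k + 1][0]
        assert work[d : d + 2] == "GT" and work[a - 2 : a] == "AG", "non-canonical intron"
    return GeneModel(
        gene_id=f"{locus_id}.g",
        locus_id=locus_id,
        scaffold_id=scaffold_id,
        strand=strand,
        exons=exons,
        cds=cds,
        protein=protein,
        model_score=float(score),
        frameshift_events=fs,
        internal_stop_count=stops,
        reference_id=reference_id,
        reference_length=m,
    )


def rank_references(locus: CandidateLocus) -> list[str]:
    """Reference ids ordered by summed supporting-HSP bit score (desc)."""
    scores: dict[str, float] = {}
    for h in locus.supporting_hsps:
        scores[h.query_id] = scores.get(h.query_id, 0.0) + h.bit_score
    return sorted(scores, key=lambda q: (-scores[q], q))


def select_best_model(
    locus: CandidateLocus,
    references: dict[str, str],
    genome: dict[str, str],
    top_n: int = 5,
    scoring: ScoringScheme | None = None,
    params: SplicedParams | None = None,
) -> GeneModel | None:
    """Build models from the ``top_n`` best-supported references, keep the best.

    Ties break toward fewer frameshifts, fewer internal stops, longer
    protein, then lexicographically smaller reference id. Returns None
    (with a log record) if every candidate model is rejected.
    """
    lo, hi = locus.flanked_range
    dna = genome[locus.scaffold_id][lo:hi]
    candidates = []
    for rid in rank_references(locus)[:top_n]:
        if rid not in references or len(references[rid]) < 50:
            continue
        model = spliced_align(
            references[rid],
            dna,
            locus.strand,
            scoring=scoring,
            params=params,
            origin=lo,
            scaffold_id=locus.scaffold_id,
            locus_id=locus.locus_id,
            reference_id=rid,
        )
        if not model.rejected:
            candidates.append(model)
    if not candidates:
        log.info("locus %s: all candidate gene models rejected; locus dropped", locus.locus_id)
        return None
    candidates.sort(
        key=lambda g: (
            -g.model_score,
            g.frameshift_events,
            g.internal_stop_count,
            -len(g.protein),
            g.reference_id,
        )
    )
    return candidates[0]
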