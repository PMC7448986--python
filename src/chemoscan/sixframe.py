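"""Translated homology search of protein queries against genomic DNA.

This is the pipeline's stand-in for a tBLASTn stage: every scaffold is
translated in all six reading frames, query proteins are matched against
the translations by local Smith–Waterman alignment (Biopython's C
``PairwiseAligner``), and hits are reported as e-valued HSPs. A k-mer
seeding layer accelerates search on genome-scale frames; reported scores
are always full local-DP scores on the reported regions, because the
final alignment of every candidate window is an exhaustive local DP.

E-values use fixed ungapped Karlin–Altschul parameters for BLOSUM62
(lambda = 0.3176, K = 0.134). Absolute e-values therefore differ from
NCBI BLAST (which estimates gapped parameters), but the semantics of the
1e-5 cutoff are preserved and deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqs import AA_INDEX, revcomp, translate

VALID_QUERY_AA = frozenset("ACDEFGHIKLMNPQRSTVWYBZX")

#: Ungapped Karlin-Altschul parameters for BLOSUM62 (natural-log units).
DEFAULT_LAMBDA = 0.3176
DEFAULT_K = 0.134


def _blosum62_stop_floor(stop_score: float = -4.0):
    """BLOSUM62 with every entry involving '*' set to the mismatch floor.

    Stops in translated frames must not terminate the DP (pseudogene exons
    still need to seed hits), so '*' scores like a worst-case mismatch.
    """
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    stop = m.alphabet.index("*")
    arr[stop, :] = stop_score
    arr[:, stop] = stop_score
    out = substitution_matrices.Array(alphabet=m.alphabet, dims=2, data=arr)
    return out


@dataclass
class ScoringScheme:
    """Alignment scoring used by the search and downstream modules."""

    gap_open: float = -11.0
    gap_extend: float = -1.0
    K: float = DEFAULT_K
    lam: float = DEFAULT_LAMBDA
    matrix: object = field(default_factory=_blosum62_stop_floor)

    def __post_init__(self):
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be non-positive")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def aligner(self) -> PairwiseAligner:
        a = PairwiseAligner()
        a.mode = "local"
        a.substitution_matrix = self.matrix
        a.open_gap_score = self.gap_open + self.gap_extend
        a.extend_gap_score = self.gap_extend
        return a

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)


@dataclass
class HSP:
    """One local alignment between a protein query and a translated frame."""

    query_id: str
    scaffold_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse
    query_range: tuple[int, int]  # aa, 0-based half-open
    subject_range: tuple[int, int]  # genomic bp, forward strand, 0-based half-open
    strand: str
    raw_score: float
    bit_score: float
    evalue: float
    pident: float = 0.0
    aln_length: int = 0

    def __post_init__(self):
        if (self.frame > 0) != (self.strand == "+"):
            raise ValueError("frame sign must match strand")


@dataclass
class FrameTranslation:
    """One reading frame of one scaffold, with its coordinate map."""

    scaffold_id: str
    frame: int
    offset: int  # 0..2 within the (possibly reverse-complemented) scaffold
    protein: str
    scaffold_length: int

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    def to_genomic(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Map an aa interval [aa_start, aa_end) to forward-strand bp."""
        if self.frame > 0:
            return self.offset + 3 * aa_start, self.offset + 3 * aa_end
        L = self.scaffold_length
        return L - (self.offset + 3 * aa_end), L - (self.offset + 3 * aa_start)


def six_frame_translate(dna: str, scaffold_id: str = "seq") -> list[FrameTranslation]:
    """Translate ``dna`` in all six frames.

    Frames +1..+3 read the forward strand starting at offsets 0..2;
    frames -1..-3 read the reverse complement at offsets 0..2. Codons
    containing N translate to X; stops are kept as '*'.
    """
    L = len(dna)
    out = []
    fwd = dna.upper()
    rev = revcomp(fwd)
    for off in range(3):
        out.append(FrameTranslation(scaffold_id, off + 1, off, translate(fwd[off:]), L))
    for off in range(3):
        out.append(FrameTranslation(scaffold_id, -(off + 1), off, translate(rev[off:]), L))
    return out


class GenomeIndex:
    """Six-frame translations of a scaffold set plus a protein k-mer index.

    Build once per genome and pass to :func:`search` for repeated queries.
    """

    def __init__(self, genome: dict[str, str], k: int = 5):
        self.k = k
        self.frames: list[FrameTranslation] = []
        for sid, seq in genome.items():
            self.frames.extend(six_frame_translate(seq, sid))
        self.total_aa = sum(len(f.protein) for f in self.frames)
        self._kmer_index = None

    def _build_kmer_index(self):
        k = self.k
        codes_all, frames_all, pos_all = [], [], []
        for fi, fr in enumerate(self.frames):
            enc = _encode_protein(fr.protein)
            if len(enc) < k:
                continue
            codes = _kmer_codes(enc, k)
            valid = codes >= 0
            idx = np.nonzero(valid)[0].astype(np.int32)
            codes_all.append(codes[valid])
            frames_all.append(np.full(len(idx), fi, dtype=np.int32))
            pos_all.append(idx)
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self._kmer_index = (
                codes[order],
                np.concatenate(frames_all)[order],
                np.concatenate(pos_all)[order],
            )
        else:
            self._kmer_index = (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int32),
                np.empty(0, dtype=np.int32),
            )

    def kmer_hits(self, query_enc: np.ndarray):
        """All (query_pos, frame_idx, frame_pos) exact k-mer matches."""
        if self._kmer_index is None:
            self._build_kmer_index()
        codes, frames, pos = self._kmer_index
        qcodes = _kmer_codes(query_enc, self.k)
        qp_out, fr_out, fp_out = [], [], []
        for qp, code in enumerate(qcodes):
            if code < 0:
                continue
            lo = np.searchsorted(codes, code, side="left")
            hi = np.searchsorted(codes, code, side="right")
            if hi > lo:
                qp_out.append(np.full(hi - lo, qp, dtype=np.int32))
                fr_out.append(frames[lo:hi])
                fp_out.append(pos[lo:hi])
        if not qp_out:
            z = np.empty(0, dtype=np.int32)
            return z, z, z
        return np.concatenate(qp_out), np.concatenate(fr_out), np.concatenate(fp_out)


def _encode_protein(protein: str) -> np.ndarray:
    enc = np.full(len(protein), -1, dtype=np.int8)
    for i, a in enumerate(protein):
        enc[i] = AA_INDEX.get(a, -1)
    return enc


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """Base-20 codes of all k-mers; windows containing non-standard aa get -1."""
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    e = enc.astype(np.int64)
    for t in range(k):
        codes = codes * 20 + np.maximum(e[t : t + n], 0)
        bad |= e[t : t + n] < 0
    codes[bad] = -1
    return codes


def _cluster_seeds(qpos, fpos, diag_tol=10, pos_gap=200):
    """Group seed hits of one frame into diagonal clusters."""
    diag = fpos - qpos
    order = np.lexsort((fpos, diag))
    clusters = []
    cur = []
    last_d = last_p = None
    for i in order:
        d, p = int(diag[i]), int(fpos[i])
        if cur and (d - last_d > diag_tol or (d == last_d and p - last_p > pos_gap)):
            clusters.append(cur)
            cur = []
        if cur and d - diag[cur[0]] > diag_tol:
            clusters.append(cur)
            cur = []
        cur.append(i)
        last_d, last_p = d, p
    if cur:
        clusters.append(cur)
    return clusters


def _hsps_from_alignment(aln, query_id, fr: FrameTranslation, win_off, scoring, m, n_total):
    """Convert one PairwiseAligner local alignment into an HSP."""
    qa, sa = aln.aligned  # blocks: [[qs,qe],...], [[ss,se],...] target=query
    if len(qa) == 0:
        return None
    q0, q1 = int(qa[0][0]), int(qa[-1][1])
    s0, s1 = int(sa[0][0]) + win_off, int(sa[-1][1]) + win_off
    # percent identity and alignment length over all columns
    tgt, qry = str(aln[0]), str(aln[1])
    ident = sum(1 for a, b in zip(tgt, qry) if a == b and a != "-")
    length = len(tgt)
    raw = float(aln.score)
    ev = scoring.evalue(raw, m, n_total)
    return HSP(
        query_id=query_id,
        scaffold_id=fr.scaffold_id,
        frame=fr.frame,
        query_range=(q0, q1),
        subject_range=fr.to_genomic(s0, s1),
        strand=fr.strand,
        raw_score=raw,
        bit_score=scoring.bit_score(raw),
        evalue=ev,
        pident=100.0 * ident / max(length, 1),
        aln_length=length,
    )


def search(
    query: str,
    genome,
    scoring: ScoringScheme | None = None,
    evalue_cutoff: float = 1e-5,
    query_id: str = "query",
    full_dp_max_aa: int = 3000,
    min_seeds: int = 2,
    window_pad: int = 30,
) -> list[HSP]:
    """Search one protein query against a scaffold set.

    ``genome`` is either a ``dict`` of scaffold sequences or a prebuilt
    :class:`GenomeIndex`. Frames shorter than ``full_dp_max_aa`` are
    aligned exhaustively; longer frames go through k-mer seeding (exact
    5-mer hits, diagonal clustering, ``min_seeds`` seeds per cluster)
    followed by exhaustive local DP on each candidate window, so reported
    scores always equal full DP scores on the reported regions.
    """
    if scoring is None:
        scoring = ScoringScheme()
    query = query.upper().rstrip("*")
    bad = set(query) - VALID_QUERY_AA
    if bad:
        raise ValueError(f"query contains non-amino-acid symbols: {sorted(bad)}")
    if len(query) < 10:
        raise ValueError("query must be at least 10 aa")

    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    aligner = scoring.aligner()
    m = len(query)
    n_total = index.total_aa
    hsps: list[HSP] = []

    small = [
        (fi, fr) for fi, fr in enumerate(index.frames) if len(fr.protein) <= full_dp_max_aa
    ]
    large = {fi for fi, fr in enumerate(index.frames) if len(fr.protein) > full_dp_max_aa}

    for _fi, fr in small:
        if len(fr.protein) < 3:
            continue
        alns = aligner.align(query, fr.protein)
        if alns.score <= 0:
            continue
        h = _hsps_from_alignment(alns[0], query_id, fr, 0, scoring, m, n_total)
        if h is not None:
            hsps.append(h)

    if large:
        q_enc = _encode_protein(query)
        qp, fidx, fpos = index.kmer_hits(q_enc)
        sel = np.isin(fidx, np.fromiter(large, dtype=np.int32)) if len(fidx) else slice(0)
        qp, fidx, fpos = qp[sel], fidx[sel], fpos[sel]
        for fi in np.unique(fidx):
            fr = index.frames[int(fi)]
            mask = fidx == fi
            clusters = _cluster_seeds(qp[mask], fpos[mask])
            windows = []
            for cl in clusters:
                if len(cl) < min_seeds:
                    continue
                fp = fpos[mask][cl]
                qq = qp[mask][cl]
                lo = int(np.min(fp - qq)) - window_pad
                hi = int(np.max(fp + (m - qq))) + window_pad
                windows.append((max(lo, 0), min(hi, len(fr.protein))))
            windows.sort()
            merged = []
            for lo, hi in windows:
                if merged and lo <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
                else:
                    merged.append((lo, hi))
            for lo, hi in merged:
                sub = fr.protein[lo:hi]
                if len(sub) < 3:
                    continue
                alns = aligner.align(query, sub)
                if alns.score <= 0:
                    continue
                h = _hsps_from_alignment(alns[0], query_id, fr, lo, scoring, m, n_total)
                if h is not None:
                    hsps.append(h)

    hsps = [h for h in hsps if h.evalue <= evalue_cutoff]
    # dedupe identical regions found via overlapping windows
    seen = {}
    for h in hsps:
        key = (h.scaffold_id, h.frame, h.query_range, h.subject_range)
        if key not in seen or h.raw_score > seen[key].raw_score:
            seen[key] = h
    hsps = list(seen.values())
    hsps.sort(key=lambda h: (h.scaffold_id, h.subject_range[0], h.subject_range[1]))
    return hsps


def search_many(
    queries: dict[str, str], genome, scoring=None, evalue_cutoff: float = 1e-5, **kw
) -> list[HSP]:
    """Search several queries against one (shared) genome index."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    out = []
    for qid, seq in queries.items():
        out.extend(
            search(seq, index, scoring, evalue_cutoff=evalue_cutoff, query_id=qid, **kw)
        )
    return out


def write_blast_tab(hsps: list[HSP], path) -> None:
    """BLAST outfmt-6-style TSV (1-based inclusive coordinates) + frame."""
    with open(path, "w") as fh:
        for h in hsps:
            qs, qe = h.query_range
            ss, se = h.subject_range
            if h.strand == "+":
                s1, s2 = ss + 1, se
            else:  # BLAST reports minus-strand subject coords descending
                s1, s2 = se, ss + 1
            fh.write(
                f"{h.query_id}\t{h.scaffold_id}\t{h.pident:.2f}\t{h.aln_length}\t"
                f"{qs + 1}\t{qe}\t{s1}\t{s2}\t{h.evalue:.3g}\t{h.bit_score:.1f}\t{h.frame}\n"
            )
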