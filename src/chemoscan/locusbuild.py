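"""Chain HSPs exon-by-exon into candidate gene loci and attach flanks.

Two HSPs join the same chain iff they lie on the same scaffold and
strand, their genomic gap is at most ``max_intron``, their query
intervals are colinear with genomic order on the coding strand (overlap
of at most 10 aa tolerated), and the chain span stays within
``max_locus_span``. A repeat of already-covered query region inside one
chain (coverage reset) forces a split, which keeps adjacent tandem
duplicates from fusing into one locus. Chains from different queries
whose genomic ranges overlap are merged into a single locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .sixframe import HSP

DEFAULT_MAX_INTRON = 15_000
DEFAULT_MAX_LOCUS_SPAN = 50_000
QUERY_OVERLAP_TOL = 10  # aa


@dataclass
class CandidateLocus:
    locus_id: str
    scaffold_id: str
    strand: str
    core_range: tuple[int, int]
    flanked_range: tuple[int, int]
    supporting_hsps: list[HSP] = field(default_factory=list)
    best_query: str | None = None

    def span(self) -> int:
        return self.core_range[1] - self.core_range[0]


def _coding_order_key(hsp: HSP):
    # order along the coding strand: forward = ascending genomic,
    # reverse = descending genomic
    s, e = hsp.subject_range
    return s if hsp.strand == "+" else -e


def _chain_query_hsps(hsps, max_intron, max_locus_span):
    """Chain the HSPs of one (scaffold, strand, query) greedily in coding order."""
    hsps = sorted(hsps, key=_coding_order_key)
    chains = []
    cur = []
    for h in hsps:
        if not cur:
            cur = [h]
            continue
        prev = cur[-1]
        if prev.strand == "+":
            gap = h.subject_range[0] - prev.subject_range[1]
        else:
            gap = prev.subject_range[0] - h.subject_range[1]
        lo = min(min(x.subject_range[0] for x in cur), h.subject_range[0])
        hi = max(max(x.subject_range[1] for x in cur), h.subject_range[1])
        colinear = h.query_range[0] >= prev.query_range[1] - QUERY_OVERLAP_TOL
        coverage_reset = h.query_range[0] < prev.query_range[0]
        if gap <= max_intron and colinear and not coverage_reset and hi - lo <= max_locus_span:
            cur.append(h)
        else:
            chains.append(cur)
            cur = [h]
    if cur:
        chains.append(cur)
    return chains


def chain_hits(
    hsps: list[HSP],
    max_intron: int = DEFAULT_MAX_INTRON,
    max_locus_span: int = DEFAULT_MAX_LOCUS_SPAN,
) -> list[CandidateLocus]:
    """Build candidate loci from HSPs; every HSP lands in exactly one locus."""
    groups: dict[tuple, list[HSP]] = {}
    for h in hsps:
        groups.setdefault((h.scaffold_id, h.strand, h.query_id), []).append(h)

    # per-query chains, then merge overlapping chains across queries
    by_region: dict[tuple, list[list[HSP]]] = {}
    for (sc, st, _q), hs in sorted(groups.items()):
        for chain in _chain_query_hsps(hs, max_intron, max_locus_span):
            by_region.setdefault((sc, st), []).append(chain)

    loci = []
    for (sc, st), chains in sorted(by_region.items()):
        intervals = []
        for chain in chains:
            lo = min(h.subject_range[0] for h in chain)
            hi = max(h.subject_range[1] for h in chain)
            intervals.append((lo, hi, chain))
        intervals.sort(key=lambda x: (x[0], x[1]))
        merged: list[list] = []
        for lo, hi, chain in intervals:
            if merged and lo < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
                merged[-1][2].extend(chain)
            else:
                merged.append([lo, hi, list(chain)])
        for lo, hi, chain in merged:
            loci.append(_make_locus(sc, st, (lo, hi), chain))

    loci.sort(key=lambda l: (l.scaffold_id, l.core_range[0], l.strand))
    for i, loc in enumerate(loci):
        loc.locus_id = f"locus_{i + 1:04d}"
    return loci


def _make_locus(scaffold, strand, core, chain) -> CandidateLocus:
    scores: dict[str, float] = {}
    for h in chain:
        scores[h.query_id] = scores.get(h.query_id, 0.0) + h.bit_score
    best = max(sorted(scores), key=lambda q: scores[q])
    return CandidateLocus(
        locus_id="",
        scaffold_id=scaffold,
        strand=strand,
        core_range=core,
        flanked_range=core,
        supporting_hsps=sorted(chain, key=lambda h: (h.subject_range, h.query_id)),
        best_query=best,
    )


def add_flanks(locus: CandidateLocus, scaffold_length: int, flank: int = 2000) -> CandidateLocus:
    """Extend the core range by ``flank`` bp each side, clipped to the scaffold."""
    lo = max(0, locus.core_range[0] - flank)
    hi = min(scaffold_length, locus.core_range[1] + flank)
    return replace(locus, flanked_range=(lo, hi))


def merge_rounds(loci_round1: list[CandidateLocus], loci_round2: list[CandidateLocus]) -> list[CandidateLocus]:
    """Unify loci from two identification rounds.

    Loci whose core ranges overlap on the same scaffold and strand are
    merged into the envelope of both; ids of round-1 survivors are kept.
    """
    out: list[tuple[CandidateLocus, int]] = []  # (locus, round-of-origin; 1 wins)
    pool = sorted(
        [(l, 1) for l in loci_round1] + [(l, 2) for l in loci_round2],
        key=lambda x: (x[0].scaffold_id, x[0].strand, x[0].core_range),
    )
    for loc, rnd in pool:
        if out:
            prev, prev_rnd = out[-1]
            if (
                prev.scaffold_id == loc.scaffold_id
                and prev.strand == loc.strand
                and loc.core_range[0] < prev.core_range[1]
            ):
                core = (
                    min(prev.core_range[0], loc.core_range[0]),
                    max(prev.core_range[1], loc.core_range[1]),
                )
                flanked = (
                    min(prev.flanked_range[0], loc.flanked_range[0]),
                    max(prev.flanked_range[1], loc.flanked_range[1]),
                )
                seen_keys = {
                    (h.query_id, h.subject_range, h.frame) for h in prev.supporting_hsps
                }
                merged_hsps = prev.supporting_hsps + [
                    h
                    for h in loc.supporting_hsps
                    if (h.query_id, h.subject_range, h.frame) not in seen_keys
                ]
                unified = _make_locus(prev.scaffold_id, prev.strand, core, merged_hsps)
                unified.flanked_range = flanked
                if prev_rnd == 1:
                    unified.locus_id = prev.locus_id
                elif rnd == 1:
                    unified.locus_id = loc.locus_id
                out[-1] = (unified, min(prev_rnd, rnd))
                continue
        out.append((replace(loc), rnd))
    result = []
    nxt = 1
    for loc, rnd in out:
        if rnd == 2:  # fresh ids for loci that came only from round 2
            loc.locus_id = f"locus_r2_{nxt:04d}"
            nxt += 1
        result.append(loc)
    return result


def write_bed(loci: list[CandidateLocus], path) -> None:
    """Locus BED (0-based half-open) with id, strand, best query, HSP count."""
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.scaffold_id}\t{l.core_range[0]}\t{l.core_range[1]}\t"
                f"{l.locus_id}\t{len(l.supporting_hsps)}\t{l.strand}\t{l.best_query}\n"
            )
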