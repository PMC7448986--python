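"""Dynamic-programming kernel for spliced protein-to-genome alignment.

Local alignment of a reference protein to (coding-strand) genomic DNA
with states for codon match, codon insertion/deletion (affine, 3-bp
steps), single-base frameshifts, internal stop codons (scored, not
terminating), and introns: zero-length-cost jumps permitted only between
codons, from a GT donor to an AG acceptor at least ``min_intron`` bp
downstream, charged a flat penalty.

The kernel fills pointer matrices; traceback happens in Python.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = np.float32(-1e30)

# M-state traceback codes
M_NONE = 0
M_START = 1
M_FROM_M = 2
M_FROM_IX = 3
M_FROM_IY = 4
M_FS2 = 5  # 2-bp codon (frameshift)
M_FS1 = 6  # skip 1 bp (frameshift)
M_INTRON = 7


@njit(cache=True)
def fill(
    n,
    m,
    sub_of,  # float32[m+1, n+1]: sub_of[i, j] = score of protein aa i vs codon s[j-3:j]
    is_gt,  # bool[n+1]: GT starts at position j (j <= n-2)
    is_ag_end,  # bool[n+1]: AG occupies s[j-2:j]
    gap_open_step,  # cost of first gap codon (open+extend)
    gap_extend,
    fs_pen,
    intron_pen,
    min_intron,
):
    M = np.full((2, n + 1), np.float32(0.0), dtype=np.float32)
    Ix = np.full((2, n + 1), NEG, dtype=np.float32)
    Iy = np.full((2, n + 1), NEG, dtype=np.float32)
    tbM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbIx = np.zeros((m + 1, n + 1), dtype=np.uint8)
    tbIy = np.zeros((m + 1, n + 1), dtype=np.uint8)
    donor_ptr = np.zeros((m + 1, n + 1), dtype=np.int32)

    donor_best = np.full(n + 1, NEG, dtype=np.float32)
    donor_arg = np.zeros(n + 1, dtype=np.int32)

    best_score = np.float32(0.0)
    best_i = 0
    best_j = 0

    for i in range(1, m + 1):
        cur = i & 1
        prv = 1 - cur
        # reset donor tracking for this row
        for j in range(n + 1):
            donor_best[j] = NEG
            donor_arg[j] = 0
        M[cur, 0] = 0.0
        Ix[cur, 0] = NEG
        Iy[cur, 0] = np.float32(max(M[prv, 0] + gap_open_step, Iy[prv, 0] + gap_extend))
        tbIy[i, 0] = 0 if M[prv, 0] + gap_open_step >= Iy[prv, 0] + gap_extend else 1
        if is_gt[0]:
            donor_best[0] = M[cur, 0]
            donor_arg[0] = 0
        for j in range(1, n + 1):
            # ---- M state ----
            best = np.float32(0.0)
            ptr = M_NONE
            if j >= 3:
                s = sub_of[i, j]
                prev_best = np.float32(0.0)
                src = M_START
                if M[prv, j - 3] > prev_best:
                    prev_best = M[prv, j - 3]
                    src = M_FROM_M
                if Ix[prv, j - 3] > prev_best:
                    prev_best = Ix[prv, j - 3]
                    src = M_FROM_IX
                if Iy[prv, j - 3] > prev_best:
                    prev_best = Iy[prv, j - 3]
                    src = M_FROM_IY
                cand = prev_best + s
                if cand > best:
                    best = cand
                    ptr = src
            if j >= 2:
                cand = M[prv, j - 2] + fs_pen
                if cand > best:
                    best = cand
                    ptr = M_FS2
            cand = M[cur, j - 1] + fs_pen
            if cand > best:
                best = cand
                ptr = M_FS1
            if is_ag_end[j] and j >= min_intron:
                d = j - min_intron
                if donor_best[d] > NEG / 2:
                    cand = donor_best[d] + intron_pen
                    if cand > best:
                        best = cand
                        ptr = M_INTRON
                        donor_ptr[i, j] = donor_arg[d]
            M[cur, j] = best
            tbM[i, j] = ptr
            if best > best_score:
                best_score = best
                best_i = i
                best_j = j
            # ---- donor running max (donor at codon boundary j, GT at j) ----
            if is_gt[j] and M[cur, j] > donor_best[j - 1]:
                donor_best[j] = M[cur, j]
                donor_arg[j] = j
            else:
                donor_best[j] = donor_best[j - 1]
                donor_arg[j] = donor_arg[j - 1]
            # ---- Ix: consume a genome codon with no protein residue ----
            if j >= 3:
                op = M[cur, j - 3] + gap_open_step
                ex = Ix[cur, j - 3] + gap_extend
                if op >= ex:
                    Ix[cur, j] = op
                    tbIx[i, j] = 0
                else:
                    Ix[cur, j] = ex
                    tbIx[i, j] = 1
            else:
                Ix[cur, j] = NEG
            # ---- Iy: consume a protein residue with no genome ----
            op = M[prv, j] + gap_open_step
            ex = Iy[prv, j] + gap_extend
            if op >= ex:
                Iy[cur, j] = op
                tbIy[i, j] = 0
            else:
                Iy[cur, j] = ex
                tbIy[i, j] = 1
        # donor_best at j=0 handled above; nothing else per row
    return best_score, best_i, best_j, tbM, tbIx, tbIy, donor_ptr
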