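"""Independent reference implementations used only to check the package.

These deliberately take different routes from the library code: the
Smith-Waterman oracle is a plain Gotoh DP over explicit loops, the
six-frame oracle goes through Biopython's translator, and the codon
log-likelihood oracle sums categories and states directly with
``scipy.linalg.expm`` and numerically integrated beta category means.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import beta as beta_dist

NEG = float("-inf")


def sw_score(query: str, subject: str, matrix, open_total: float, extend: float) -> float:
    """Best local alignment score, affine gaps (first gap residue costs
    ``open_total``, later ones ``extend``); ``matrix[a, b]`` scores a pair."""
    m, n = len(query), len(subject)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consume subject)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (consume query)
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] + open_total, E[i][j - 1] + extend)
            F[i][j] = max(H[i - 1][j] + open_total, F[i - 1][j] + extend)
            s = matrix[query[i - 1], subject[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def six_frames_biopython(dna: str) -> list[str]:
    """Frames +1..+3 then -1..-3, stops as '*', via Biopython."""
    fwd = Seq(dna)
    rev = fwd.reverse_complement()
    out = []
    for seq in (fwd, rev):
        for off in range(3):
            sub = seq[off:]
            sub = sub[: 3 * (len(sub) // 3)]
            out.append(str(sub.translate()))
    return out


def beta_category_means_quad(p: float, q: float, K: int) -> np.ndarray:
    """Category means by numerical integration (independent of betainc)."""
    edges = beta_dist.ppf(np.linspace(0, 1, K + 1), p, q)
    means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(lambda x: x * beta_dist.pdf(x, p, q), lo, hi, limit=200)
        means.append(val * K)
    return np.array(means)


def codon_loglik_bruteforce(aln, model: str, t, kappa, p, q, p0=1.0, omega_s=2.0, K=10):
    """Direct mixture log-likelihood: expm per category, explicit site loop."""
    from chemoscan.codonmodel import CODON_INDEX, N_CODONS, rate_matrix

    means = beta_category_means_quad(p, q, K)
    if model == "M7":
        weights = [1.0 / K] * K
        omegas = list(means)
    else:
        weights = [p0 / K] * K + [1.0 - p0]
        omegas = list(means) + [omega_s]
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    Qs = [rate_matrix(kappa, om, pi) for om in omegas]
    mu = sum(w * -(pi * np.diag(Q)).sum() for w, Q in zip(weights, Qs))
    Ps = [expm(Q * t / mu) for Q in Qs]
    ll = 0.0
    for ca, cb in zip(aln.codons_a, aln.codons_b):
        if ca not in CODON_INDEX or cb not in CODON_INDEX:
            continue
        x, y = CODON_INDEX[ca], CODON_INDEX[cb]
        site = sum(w * pi[x] * P[x, y] for w, P in zip(weights, Ps))
        ll += np.log(site)
    return ll
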