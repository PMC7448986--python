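"""GY94-style codon substitution machinery shared by the simulator and
the site-model fitter.

The model acts on the 61 sense codons of the universal code. The
instantaneous rate between codons differing at exactly one nucleotide is
proportional to the target codon frequency, multiplied by kappa for
transitions and by omega for nonsynonymous changes; multi-nucleotide
changes have rate zero. Site-to-site variation in omega follows the M7 /
M8 mixtures: omega ~ beta(p, q) discretized into K equal-probability
categories (category means), with M8 adding one extra class at
omega_s > 1 carrying weight 1 - p0. Branch length t is the expected
number of substitutions per codon averaged over the mixture.

Default stationary frequencies are uniform over the 61 sense codons,
which keeps the matrix reversible-symmetric and the simulator and fitter
self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from .seqs import CODON_TABLE, STOP_CODONS

SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

_PURINES = {"A", "G"}


def _pair_classification():
    """For each single-nucleotide codon pair: is it a transition / nonsyn?"""
    n = N_CODONS
    single = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = (a in _PURINES) == (b in _PURINES)
            nonsyn[i, j] = CODON_TABLE[ci] != CODON_TABLE[cj]
    return single, transition, nonsyn


_SINGLE, _TRANSITION, _NONSYN = _pair_classification()

# structural parts: synonymous/nonsynonymous x transversion/transition
_S_TV = (_SINGLE & ~_TRANSITION & ~_NONSYN).astype(float)
_S_TS = (_SINGLE & _TRANSITION & ~_NONSYN).astype(float)
_N_TV = (_SINGLE & ~_TRANSITION & _NONSYN).astype(float)
_N_TS = (_SINGLE & _TRANSITION & _NONSYN).astype(float)


def rate_matrix(kappa: float, omega: float, pi: np.ndarray | None = None) -> np.ndarray:
    """Unnormalized GY94 rate matrix Q (rows sum to zero)."""
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    Q = (_S_TV + kappa * _S_TS + omega * _N_TV + (kappa * omega) * _N_TS) * pi[None, :]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(Q: np.ndarray, pi: np.ndarray | None = None) -> float:
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    return float(-(pi * np.diag(Q)).sum())


def transition_matrix(Q: np.ndarray, t: float, pi: np.ndarray | None = None) -> np.ndarray:
    """P(t) = exp(Qt) via symmetrized eigendecomposition (Q reversible)."""
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    rt = np.sqrt(pi)
    B = Q * (rt[:, None] / rt[None, :])
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    E = U * np.exp(w * t)[None, :]
    P = (E @ U.T) * (rt[None, :] / rt[:, None])
    np.maximum(P, 0.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def beta_category_means(p: float, q: float, K: int = 10) -> np.ndarray:
    """Means of K equal-probability slices of beta(p, q)."""
    edges = beta_dist.ppf(np.linspace(0.0, 1.0, K + 1), p, q)
    upper = betainc(p + 1.0, q, edges[1:])
    lower = betainc(p + 1.0, q, edges[:-1])
    means = (p / (p + q)) * (upper - lower) * K
    return np.clip(means, 0.0, 1.0)


def site_classes(
    model: str,
    beta_p: float,
    beta_q: float,
    p0: float = 1.0,
    omega_s: float = 2.0,
    K: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """(weights, omegas) of the mixture; M7 = beta only, M8 adds omega_s."""
    means = beta_category_means(beta_p, beta_q, K)
    if model == "M7":
        return np.full(K, 1.0 / K), means
    if model == "M8":
        w = np.concatenate([np.full(K, p0 / K), [1.0 - p0]])
        om = np.concatenate([means, [omega_s]])
        return w, om
    raise ValueError(f"unknown site model {model!r}")


def class_transition_matrices(
    t: float,
    kappa: float,
    weights: np.ndarray,
    omegas: np.ndarray,
    pi: np.ndarray | None = None,
) -> np.ndarray:
    """P_c(t) for every omega class (stacked, shape (C, 61, 61)), scaled so
    the mixture-average substitution rate is 1."""
    uniform = pi is None or float(np.ptp(pi)) == 0.0
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    if uniform:  # symmetric Q: eigendecomposition reusable across t
        w, U, rates = _class_eigs(kappa, tuple(float(o) for o in omegas))
        mu = float((np.asarray(weights) * rates).sum())
        if mu <= 0:
            mu = 1e-12
        E = np.exp(w * (t / mu))
        P = (U * E[:, None, :]) @ U.transpose(0, 2, 1)
        np.maximum(P, 0.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P
    Qs = np.stack([rate_matrix(kappa, om, pi) for om in omegas])
    mu = float(np.einsum("c,cii,i->", np.asarray(weights), -Qs, pi))
    if mu <= 0:
        mu = 1e-12
    return np.stack([transition_matrix(Q, t / mu, pi) for Q in Qs])


_EIG_CACHE: dict[tuple, tuple] = {}


def _class_eigs(kappa: float, omegas: tuple):
    """Cached eigensystems (w, U, per-class mean rates) of the uniform-pi
    rate matrices for one (kappa, omega-set); per-omega entries are cached
    individually so BEB grids and optimizer gradient steps reuse them."""
    out_w, out_U, out_r = [], [], []
    for om in omegas:
        key = (round(kappa, 12), round(om, 12))
        hit = _EIG_CACHE.get(key)
        if hit is None:
            Q = rate_matrix(kappa, om)
            pi = np.full(N_CODONS, 1.0 / N_CODONS)
            r = float(-(pi * np.diag(Q)).sum())
            w, U = np.linalg.eigh(Q)
            if len(_EIG_CACHE) > 4096:
                _EIG_CACHE.clear()
            hit = _EIG_CACHE[key] = (w, U, r)
        out_w.append(hit[0])
        out_U.append(hit[1])
        out_r.append(hit[2])
    return np.stack(out_w), np.stack(out_U), np.array(out_r)


@dataclass
class CodonSimSpec:
    """Conditions for simulating a pairwise codon alignment."""

    model: str = "M7"  # M7 | M8
    n_codons: int = 300
    t: float = 0.5  # expected substitutions/codon between the two sequences
    kappa: float = 2.0
    beta_p: float = 0.5
    beta_q: float = 1.5
    p0: float = 1.0  # beta-class weight (M8 only)
    omega_s: float = 2.0  # selected-class omega (M8 only; > 1)
    n_replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if self.model == "M8" and self.omega_s <= 1.0:
            raise ValueError("omega_s must exceed 1 under M8")
        if self.t < 0:
            raise ValueError("t must be non-negative")
        if self.model not in ("M7", "M8"):
            raise ValueError("model must be M7 or M8")


def simulate_codon_pair(
    spec: CodonSimSpec, rng: np.random.Generator | None = None
) -> tuple[tuple[str, str], np.ndarray]:
    """Evolve a codon-sequence pair under the beta(-plus-selection) mixture.

    The ancestor is drawn at stationarity and one lineage is evolved for
    branch length t (by reversibility this equals splitting t between the
    two). Returns the two codon sequences and the per-site true class
    index (the last class is the selected one under M8).
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    weights, omegas = site_classes(
        spec.model, spec.beta_p, spec.beta_q, spec.p0, spec.omega_s
    )
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    cats = rng.choice(len(weights), size=spec.n_codons, p=weights)
    anc = rng.choice(N_CODONS, size=spec.n_codons, p=pi)
    if spec.t == 0:
        der = anc.copy()
    else:
        Ps = class_transition_matrices(spec.t, spec.kappa, weights, omegas, pi)
        der = np.empty_like(anc)
        for c, P in enumerate(Ps):
            mask = cats == c
            if not mask.any():
                continue
            cum = np.cumsum(P[anc[mask]], axis=1)
            u = rng.random(mask.sum())
            der[mask] = (u[:, None] > cum).sum(axis=1)
    seq_a = "".join(SENSE_CODONS[i] for i in anc)
    seq_b = "".join(SENSE_CODONS[i] for i in der)
    return (seq_a, seq_b), cats
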