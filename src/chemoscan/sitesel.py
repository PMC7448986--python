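"""Pairwise codon site-model positive-selection analysis.

For each orthologue pair: a protein-guided codon alignment, maximum
likelihood fits of the M7 (beta) and M8 (beta plus omega > 1) site
models, the likelihood-ratio test Delta = 2(lnL_M8 - lnL_M7) referred
to a chi-square distribution (df = 1 by default, as in the annotation
protocol this package follows; df = 2 is available), and per-site
posterior probabilities of the selected class by naive empirical Bayes
(at the MLEs) and Bayes empirical Bayes (averaging over a parameter
grid weighted by the data likelihood under a uniform prior). A gene
pair is called positively selected iff the LRT P-value is below 0.01
and at least one site reaches posterior 0.95 under both NEB and BEB.

The substitution process is the GY94-style codon model of
:mod:`chemoscan.codonmodel` with uniform codon frequencies by default,
shared verbatim with the simulator, and K = 10 equal-probability beta
categories (category means).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonmodel import (
    CODON_INDEX,
    N_CODONS,
    SENSE_CODONS,
    class_transition_matrices,
    site_classes,
)
from .seqs import STOP_CODONS, translate

log = logging.getLogger(__name__)

BOUNDS = {
    "t": (1e-4, 20.0),
    "kappa": (0.1, 20.0),
    "p": (0.05, 50.0),
    "q": (0.05, 50.0),
    "p0": (0.0, 1.0),
    "omega_s": (1.0, 20.0),
}
K_CATEGORIES = 10


@dataclass
class CodonAlignment:
    ids: tuple[str, str]
    codons_a: list[str]  # aligned codon columns, '---' = gap
    codons_b: list[str]

    def __post_init__(self):
        if len(self.codons_a) != len(self.codons_b):
            raise ValueError("rows differ in column count")

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)

    def paired_indices(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, site_numbers) of columns where both rows carry sense codons."""
        xs, ys, sites = [], [], []
        for k, (ca, cb) in enumerate(zip(self.codons_a, self.codons_b)):
            if ca in CODON_INDEX and cb in CODON_INDEX:
                xs.append(CODON_INDEX[ca])
                ys.append(CODON_INDEX[cb])
                sites.append(k)
        return np.array(xs, dtype=np.int32), np.array(ys, dtype=np.int32), np.array(sites)

    def pair_count_matrix(self) -> np.ndarray:
        x, y, _ = self.paired_indices()
        return (
            np.bincount(x.astype(np.int64) * N_CODONS + y, minlength=N_CODONS * N_CODONS)
            .reshape(N_CODONS, N_CODONS)
            .astype(float)
        )


def codon_align(
    protein_rows: tuple[str, str],
    cds_a: str,
    cds_b: str,
    ids: tuple[str, str] = ("seq_a", "seq_b"),
) -> CodonAlignment:
    """Expand an aligned protein pair into its codon alignment.

    Each amino-acid column becomes the source codon (or '---' opposite a
    gap). Columns containing a stop codon are removed with a warning.
    X in the protein is tolerated opposite any codon.
    """
    rows = []
    for row, cds, sid in zip(protein_rows, (cds_a, cds_b), ids):
        if len(cds) % 3:
            raise ValueError(f"{sid}: CDS length not divisible by 3")
        degapped = row.replace("-", "")
        prot = translate(cds)
        if len(prot) != len(degapped):
            raise ValueError(
                f"{sid}: protein row has {len(degapped)} residues but CDS encodes {len(prot)}"
            )
        for i, (a, b) in enumerate(zip(degapped, prot)):
            if a != b and "X" not in (a, b) and b != "*":
                raise ValueError(f"{sid}: protein/CDS mismatch at residue {i + 1} ({a} vs {b})")
        rows.append(row)

    cols_a, cols_b = [], []
    ia = ib = 0
    for ca, cb in zip(rows[0], rows[1]):
        if ca == "-":
            cols_a.append("---")
        else:
            cols_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            cols_b.append("---")
        else:
            cols_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    keep_a, keep_b = [], []
    removed = 0
    for x, y in zip(cols_a, cols_b):
        if x in STOP_CODONS or y in STOP_CODONS:
            removed += 1
            continue
        keep_a.append(x)
        keep_b.append(y)
    if removed:
        warnings.warn(f"removed {removed} stop-containing codon column(s)", stacklevel=2)
    return CodonAlignment(ids=ids, codons_a=keep_a, codons_b=keep_b)


def alignment_from_pair(seq_a: str, seq_b: str, ids=("seq_a", "seq_b")) -> CodonAlignment:
    """Codon alignment of two equal-length gapless CDSs (e.g. simulated)."""
    if len(seq_a) != len(seq_b) or len(seq_a) % 3:
        raise ValueError("sequences must be equal length, divisible by 3")
    cols_a = [seq_a[i : i + 3] for i in range(0, len(seq_a), 3)]
    cols_b = [seq_b[i : i + 3] for i in range(0, len(seq_b), 3)]
    keep = [
        (x, y) for x, y in zip(cols_a, cols_b) if x not in STOP_CODONS and y not in STOP_CODONS
    ]
    return CodonAlignment(
        ids=ids, codons_a=[x for x, _ in keep], codons_b=[y for _, y in keep]
    )


@dataclass
class SiteModelFit:
    model: str
    lnL: float
    t: float
    kappa: float
    beta_p: float
    beta_q: float
    p0: float = 1.0
    omega_s: float = 1.0
    K: int = K_CATEGORIES
    converged: bool = True
    aln_key: int = 0

    def classes(self):
        return site_classes(
            "M8" if self.model == "M8" else "M7",
            self.beta_p,
            self.beta_q,
            self.p0,
            self.omega_s,
            self.K,
        )


def _loglik(counts: np.ndarray, model: str, theta: np.ndarray, K: int = K_CATEGORIES) -> float:
    if model == "M7":
        t, kappa, p, q = theta
        w, om = site_classes("M7", p, q, K=K)
    else:
        t, kappa, p, q, p0, om_s = theta
        w, om = site_classes("M8", p, q, p0, om_s, K=K)
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    Ps = class_transition_matrices(t, kappa, w, om, pi)
    mix = np.einsum("c,cij->ij", w, Ps) * pi[:, None]
    np.maximum(mix, 1e-300, out=mix)
    return float((counts * np.log(mix)).sum())


def _default_init(counts: np.ndarray, model: str) -> np.ndarray:
    n = counts.sum()
    pdiff = 1.0 - (np.trace(counts) / n if n else 1.0)
    t0 = float(np.clip(-np.log(max(1e-6, 1 - pdiff * 1.4)) * 1.2, 2e-4, 5.0))
    if model == "M7":
        return np.array([t0, 2.0, 0.8, 1.6])
    return np.array([t0, 2.0, 0.8, 1.6, 0.9, 2.0])


def fit_site_model(
    aln: CodonAlignment,
    model: str,
    n_restarts: int = 5,
    seed: int = 0,
    init: np.ndarray | None = None,
    extra_inits: list[np.ndarray] | None = None,
) -> SiteModelFit:
    """Maximize the site-model likelihood by bounded quasi-Newton with
    multi-start; the best of all starts is returned (``converged`` is
    False if no start reported optimizer success)."""
    if model not in ("M7", "M8"):
        raise ValueError("model must be M7 or M8")
    counts = aln.pair_count_matrix()
    names = ["t", "kappa", "p", "q"] + (["p0", "omega_s"] if model == "M8" else [])
    bounds = [BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)
    starts = [init if init is not None else _default_init(counts, model)]
    starts += list(extra_inits or [])
    for _ in range(max(0, n_restarts - 1)):
        s = np.array(
            [np.exp(rng.uniform(np.log(max(lo, 1e-3)), np.log(hi))) for lo, hi in bounds]
        )
        if model == "M8":
            s[4] = rng.uniform(0.4, 1.0)  # p0
            s[5] = np.clip(s[5], 1.01, 20.0)
        starts.append(np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds]))

    best = None
    any_success = False
    for s in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                lambda th: -_loglik(counts, model, th),
                s,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 300, "ftol": 1e-9},
            )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    th = best.x
    fit = SiteModelFit(
        model=model,
        lnL=-float(best.fun),
        t=float(th[0]),
        kappa=float(th[1]),
        beta_p=float(th[2]),
        beta_q=float(th[3]),
        converged=any_success,
        aln_key=id(aln),
    )
    if model == "M8":
        fit.p0 = float(th[4])
        fit.omega_s = float(th[5])
    return fit


def fit_pair(
    aln: CodonAlignment, n_restarts: int = 3, seed: int = 0
) -> tuple[SiteModelFit, SiteModelFit]:
    """Fit M7 then M8, seeding M8 from the M7 optimum (p0 -> 1) so that
    the nesting lnL(M8) >= lnL(M7) holds up to optimizer tolerance."""
    m7 = fit_site_model(aln, "M7", n_restarts=n_restarts, seed=seed)
    nested = np.array([m7.t, m7.kappa, m7.beta_p, m7.beta_q, 1.0, 1.5])
    m8 = fit_site_model(
        aln, "M8", n_restarts=n_restarts, seed=seed + 1, init=nested,
        extra_inits=[np.array([m7.t, m7.kappa, m7.beta_p, m7.beta_q, 0.7, 2.5])],
    )
    if m8.lnL < m7.lnL:  # numerical guard: M7 is an M8 boundary case
        m8 = SiteModelFit(
            model="M8", lnL=m7.lnL, t=m7.t, kappa=m7.kappa, beta_p=m7.beta_p,
            beta_q=m7.beta_q, p0=1.0, omega_s=1.5, converged=m7.converged,
            aln_key=id(aln),
        )
    return m7, m8


def lrt(fit_m7: SiteModelFit, fit_m8: SiteModelFit, df: int = 1) -> tuple[float, float]:
    """Delta = max(0, 2(lnL_M8 - lnL_M7)); upper-tail chi-square P."""
    if fit_m7.aln_key != fit_m8.aln_key:
        raise ValueError("fits come from different alignments")
    delta = max(0.0, 2.0 * (fit_m8.lnL - fit_m7.lnL))
    p = float(chi2.sf(delta, df)) if delta > 0 else 1.0
    return delta, p


def _site_class_likelihoods(aln, t, kappa, w, om):
    pi = np.full(N_CODONS, 1.0 / N_CODONS)
    Ps = class_transition_matrices(t, kappa, w, om, pi)
    x, y, sites = aln.paired_indices()
    L = np.stack([P[x, y] for P in Ps])  # (classes, paired sites)
    return L * pi[x][None, :], sites


def neb_sites(fit_m8: SiteModelFit, aln: CodonAlignment) -> np.ndarray:
    """Naive empirical Bayes P(omega > 1) per alignment column.

    Posterior over classes at the MLEs; the reported probability is the
    total weight of classes with mean omega above 1. Columns without a
    sense-codon pair get probability 0.
    """
    w, om = fit_m8.classes()
    L, sites = _site_class_likelihoods(aln, fit_m8.t, fit_m8.kappa, w, om)
    post = w[:, None] * L
    post /= np.maximum(post.sum(axis=0, keepdims=True), 1e-300)
    p_sel = post[om > 1.0].sum(axis=0)
    out = np.zeros(aln.n_codons)
    out[sites] = p_sel
    return out


def default_beb_grid() -> dict[str, np.ndarray]:
    """Six points per dimension spanning the declared fitting bounds."""
    return {
        "p0": np.linspace(0.0, 1.0, 6),
        "p": np.exp(np.linspace(np.log(0.05), np.log(50.0), 6)),
        "q": np.exp(np.linspace(np.log(0.05), np.log(50.0), 6)),
        "omega_s": np.exp(np.linspace(np.log(1.05), np.log(20.0), 6)),
    }


def beb_sites(
    fit_m8: SiteModelFit,
    aln: CodonAlignment,
    grid: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Bayes empirical Bayes P(omega > 1) per column.

    NEB-style posteriors are averaged over a discrete grid on
    (p0, p, q, omega_s) — t and kappa held at their MLEs — with each
    grid point weighted by its data likelihood under a uniform prior,
    integrating parameter uncertainty. A single-point grid at the MLEs
    reproduces NEB exactly.
    """
    if grid is None:
        grid = default_beb_grid()
    counts = aln.pair_count_matrix()
    x, y, sites = aln.paired_indices()
    pi = np.full(N_CODONS, 1.0 / N_CODONS)

    log_w_data = []
    p_sel_points = []
    for p0 in grid["p0"]:
        for p in grid["p"]:
            for q in grid["q"]:
                for om_s in grid["omega_s"]:
                    w, om = site_classes("M8", p, q, p0, om_s, K=fit_m8.K)
                    Ps = class_transition_matrices(fit_m8.t, fit_m8.kappa, w, om, pi)
                    mix = np.einsum("c,cij->ij", w, Ps) * pi[:, None]
                    np.maximum(mix, 1e-300, out=mix)
                    log_w_data.append((counts * np.log(mix)).sum())
                    Lsite = np.stack([P[x, y] for P in Ps]) * pi[x][None, :]
                    post = w[:, None] * Lsite
                    post /= np.maximum(post.sum(axis=0, keepdims=True), 1e-300)
                    p_sel_points.append(post[om > 1.0].sum(axis=0))
    log_w_data = np.array(log_w_data)
    W = np.exp(log_w_data - log_w_data.max())
    W /= W.sum()
    p_sel = (W[:, None] * np.array(p_sel_points)).sum(axis=0)
    out = np.zeros(aln.n_codons)
    out[sites] = p_sel
    return out


@dataclass
class SelectionResult:
    pair_id: str
    delta: float
    df: int
    p_value: float
    neb_posteriors: np.ndarray
    beb_posteriors: np.ndarray
    selected_sites: list[int] = field(default_factory=list)
    positively_selected: bool = False
    fit_m7: SiteModelFit | None = None
    fit_m8: SiteModelFit | None = None


def call_selection(
    pair_id: str,
    fit_m7: SiteModelFit,
    fit_m8: SiteModelFit,
    neb: np.ndarray,
    beb: np.ndarray,
    alpha: float = 0.01,
    posterior_cutoff: float = 0.95,
    df: int = 1,
) -> SelectionResult:
    """Apply the decision rule: positively selected iff P < alpha and at
    least one site passes the posterior cutoff under both NEB and BEB."""
    delta, p = lrt(fit_m7, fit_m8, df=df)
    selected = [
        int(i)
        for i in range(len(neb))
        if neb[i] >= posterior_cutoff and beb[i] >= posterior_cutoff
    ]
    return SelectionResult(
        pair_id=pair_id,
        delta=delta,
        df=df,
        p_value=p,
        neb_posteriors=neb,
        beb_posteriors=beb,
        selected_sites=selected,
        positively_selected=bool(p < alpha and selected),
        fit_m7=fit_m7,
        fit_m8=fit_m8,
    )


def analyze_pair(
    aln: CodonAlignment,
    pair_id: str = "pair",
    n_restarts: int = 3,
    seed: int = 0,
    alpha: float = 0.01,
    posterior_cutoff: float = 0.95,
    df: int = 1,
    beb_grid: dict | None = None,
) -> SelectionResult:
    """Full selection analysis of one codon alignment."""
    m7, m8 = fit_pair(aln, n_restarts=n_restarts, seed=seed)
    neb = neb_sites(m8, aln)
    beb = beb_sites(m8, aln, grid=beb_grid)
    return call_selection(
        pair_id, m7, m8, neb, beb, alpha=alpha, posterior_cutoff=posterior_cutoff, df=df
    )
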