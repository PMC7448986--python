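"""Family phylogenies and orthologue pairing.

Proteins pass family-specific length filters (ORs < 230 aa and GRs <
250 aa are excluded; IRs have no extra filter), are aligned with MAFFT,
and a neighbor-joining tree is built over maximum-likelihood JTT
distances — with gamma rate heterogeneity and empirical frequencies
(+G+F) for ORs and GRs, plain JTT for IRs. Node support is the
percentage of bootstrap replicates (column resampling, distances and NJ
recomputed) containing each bipartition. Trees are rooted on the
family's designated outgroup clade (Orco for ORs, the sugar-receptor
clade for GRs, the IR8a/25a clade for IRs). An orthologue pair is two
leaves from the two focal species whose most recent common ancestor has
exactly those two descendants.

NJ over ML distances replaces a full ML topology search: it is exact on
additive distance matrices, deterministic, and keeps the same
bootstrap/rooting/pair-extraction contract downstream.
"""

from __future__ import annotations

import io
import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from ._jtt import AA, JTT_FREQS, exchangeability_matrix

log = logging.getLogger(__name__)

AA_IDX = {a: i for i, a in enumerate(AA)}
TREE_MIN_AA = {"OR": 230, "GR": 250}
GAMMA_FAMILIES = frozenset({"OR", "GR"})  # JTT+G+F families
DEFAULT_ALPHA_GRID = (0.3, 0.5, 0.8, 1.2, 2.0, 5.0)


def filter_for_tree(proteins: dict[str, str], family: str) -> dict[str, str]:
    """Drop sequences below the family's tree length threshold."""
    cut = TREE_MIN_AA.get(family, 0)
    return {k: v for k, v in proteins.items() if len(v) >= cut}


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def degapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")

    def encoded(self) -> np.ndarray:
        """Integer matrix; gaps / non-standard aa are -1."""
        M = np.full((len(self.rows), self.n_cols), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                M[i, j] = AA_IDX.get(ch, -1)
        return M


def build_msa(proteins: dict[str, str]) -> Msa:
    """Multiple alignment via MAFFT (single-threaded, deterministic)."""
    if len(proteins) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if shutil.which("mafft") is None:
        raise RuntimeError("mafft executable not found on PATH")
    with tempfile.TemporaryDirectory() as td:
        fa = Path(td) / "in.fa"
        with open(fa, "w") as fh:
            for sid, seq in proteins.items():
                fh.write(f">{sid}\n{seq}\n")
        res = subprocess.run(
            ["mafft", "--quiet", "--anysymbol", "--thread", "1", str(fa)],
            capture_output=True,
            text=True,
            check=True,
        )
    ids, rows, cur = [], [], []
    for line in res.stdout.splitlines():
        if line.startswith(">"):
            if cur:
                rows.append("".join(cur))
                cur = []
            ids.append(line[1:].split()[0])
        else:
            cur.append(line.strip())
    if cur:
        rows.append("".join(cur))
    msa = Msa(ids=ids, rows=[r.upper() for r in rows])
    for sid, seq in proteins.items():
        if msa.degapped(sid) != seq.upper():
            raise RuntimeError(f"alignment round-trip failed for {sid}")
    return msa


# ------------------------------------------------------------ JTT distances


def _gamma_category_rates(alpha: float, K: int = 4) -> np.ndarray:
    """Means of K equal-probability slices of gamma(alpha, mean 1)."""
    edges = gamma_dist.ppf(np.linspace(0, 1, K + 1), alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, alpha * edges[1:])
    lower = gammainc(alpha + 1.0, alpha * np.nan_to_num(edges[:-1]))
    return (upper - lower) * K


class JttModel:
    """JTT(+G)(+F) pairwise ML distance machinery with a cached spectrum.

    Distances are estimated by maximizing the pairwise likelihood on a
    dense log-spaced branch-length grid followed by quadratic
    refinement; accuracy is limited by the grid (~1%), which is ample
    for tree building.
    """

    def __init__(self, alpha: float | None = None, freqs: np.ndarray | None = None,
                 K: int = 4, t_grid: np.ndarray | None = None):
        self.pi = JTT_FREQS if freqs is None else np.asarray(freqs, float)
        self.pi = self.pi / self.pi.sum()
        self.alpha = alpha
        self.rates = np.array([1.0]) if alpha is None else _gamma_category_rates(alpha, K)
        Q = exchangeability_matrix() * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -(self.pi * np.diag(Q)).sum()
        rt = np.sqrt(self.pi)
        B = Q * (rt[:, None] / rt[None, :])
        self.w, self.U = np.linalg.eigh(0.5 * (B + B.T))
        self.rt = rt
        self.t_grid = (
            np.exp(np.linspace(np.log(1e-4), np.log(12.0), 160))
            if t_grid is None
            else t_grid
        )
        self._log_mix = None

    def p_matrix(self, t: float) -> np.ndarray:
        E = self.U * np.exp(self.w * t)[None, :]
        P = (E @ self.U.T) * (self.rt[None, :] / self.rt[:, None])
        np.maximum(P, 1e-300, out=P)
        return P / P.sum(axis=1, keepdims=True)

    def _mix_joint(self, t: float) -> np.ndarray:
        """pi_a * sum_k P_k(t r_k)/K, the joint column probability."""
        M = np.zeros((20, 20))
        for r in self.rates:
            M += self.p_matrix(t * r)
        M /= len(self.rates)
        return self.pi[:, None] * M

    def log_mix_grid(self) -> np.ndarray:
        if self._log_mix is None:
            self._log_mix = np.stack(
                [np.log(self._mix_joint(t)) for t in self.t_grid]
            )
        return self._log_mix

    def loglik(self, counts: np.ndarray, t: float) -> float:
        return float((counts * np.log(self._mix_joint(t))).sum())

    def distance_from_counts(self, counts: np.ndarray) -> float:
        n = counts.sum()
        if n == 0:
            raise ValueError("no shared ungapped columns")
        if n < 30:
            log.warning("JTT distance from only %d shared columns; unreliable", int(n))
        ident = np.trace(counts)
        if ident == n:
            return 0.0
        ll = np.tensordot(self.log_mix_grid(), counts, axes=([1, 2], [0, 1]))
        k = int(np.argmax(ll))
        if 0 < k < len(self.t_grid) - 1:  # quadratic refinement in log t
            x = np.log(self.t_grid[k - 1 : k + 2])
            y = ll[k - 1 : k + 2]
            denom = (y[0] - 2 * y[1] + y[2])
            if denom < 0:
                x_hat = x[1] - 0.5 * (x[2] - x[0]) * (y[2] - y[0]) / (2 * denom)
                return float(np.exp(np.clip(x_hat, x[0], x[2])))
        return float(self.t_grid[k])


def pair_counts(enc: np.ndarray, i: int, j: int, cols: np.ndarray | None = None) -> np.ndarray:
    a = enc[i] if cols is None else enc[i][cols]
    b = enc[j] if cols is None else enc[j][cols]
    ok = (a >= 0) & (b >= 0)
    return np.bincount((a[ok].astype(np.int32) * 20 + b[ok]), minlength=400).reshape(20, 20).astype(float)


def jtt_distance(
    row_a: str,
    row_b: str,
    alpha: float | None = None,
    freqs: np.ndarray | None = None,
) -> float:
    """ML distance between two aligned rows under JTT(+G)(+F).

    Gap columns are pairwise-deleted; fewer than 30 shared columns
    triggers an unreliability warning (and an error if none remain).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must come from the same alignment")
    msa = Msa(ids=["a", "b"], rows=[row_a.upper(), row_b.upper()])
    counts = pair_counts(msa.encoded(), 0, 1)
    return JttModel(alpha=alpha, freqs=freqs).distance_from_counts(counts)


def empirical_freqs(msa: Msa) -> np.ndarray:
    enc = msa.encoded()
    counts = np.bincount(enc[enc >= 0].ravel(), minlength=20) + 1.0
    return counts / counts.sum()


def estimate_alpha(msa: Msa, freqs=None, grid=DEFAULT_ALPHA_GRID, max_pairs: int = 25) -> float:
    """Pick the gamma shape maximizing the mean pairwise likelihood."""
    enc = msa.encoded()
    n = len(msa.ids)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        step = len(pairs) // max_pairs
        pairs = pairs[::step][:max_pairs]
    counts = [pair_counts(enc, i, j) for i, j in pairs]
    best_alpha, best_ll = grid[0], -np.inf
    for alpha in grid:
        model = JttModel(alpha=alpha, freqs=freqs)
        ll = 0.0
        for c in counts:
            t = model.distance_from_counts(c)
            ll += model.loglik(c, max(t, 1e-6))
        if ll > best_ll:
            best_ll, best_alpha = ll, alpha
    return best_alpha


# ------------------------------------------------------------------- trees


@dataclass
class PhyloTree:
    tree: dendropy.Tree
    rooted: bool
    supports: dict[frozenset, float] = field(default_factory=dict)
    family: str = ""

    def leaves(self) -> list[str]:
        return [l.taxon.label for l in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True)


def _distance_matrix(model: JttModel, enc: np.ndarray, cols=None) -> np.ndarray:
    n = enc.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            c = pair_counts(enc, i, j, cols)
            if c.sum() == 0:
                d = float(model.t_grid[-1])
            else:
                d = model.distance_from_counts(c)
            D[i, j] = D[j, i] = d
    return D


def nj_tree(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining via dendropy (exact on additive matrices)."""
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{x:.10g}" for x in D[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    return pdm.nj_tree()


def _bipartitions(tree: dendropy.Tree, all_labels: frozenset) -> set[frozenset]:
    """Non-trivial splits as frozensets normalized to the smaller side."""
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_labels) - 1:
            continue
        comp = all_labels - side
        out.add(min(side, comp, key=lambda s: (len(s), tuple(sorted(s)))))
    return out


def build_tree(
    msa: Msa,
    family: str,
    n_bootstrap: int = 200,
    seed: int = 0,
    outgroup: list[str] | None = None,
    alpha: float | None = None,
    midpoint_fallback: bool = False,
) -> PhyloTree:
    """NJ tree over JTT ML distances with bootstrap supports and rooting.

    For ORs and GRs the distances use gamma rate heterogeneity (shape
    estimated from the data) and empirical frequencies; IRs use plain
    JTT. Supports are percentages of ``n_bootstrap`` column-resampled
    replicates containing each bipartition. The tree is rooted on the
    edge above the MRCA of ``outgroup``; if outgroup leaves are missing,
    an unrooted tree is returned with a warning.
    """
    if len(msa.ids) < 4:
        raise ValueError("tree building needs at least 4 sequences")
    enc = msa.encoded()
    freqs = None
    if family in GAMMA_FAMILIES:
        freqs = empirical_freqs(msa)
        if alpha is None:
            alpha = estimate_alpha(msa, freqs=freqs)
    model = JttModel(alpha=alpha, freqs=freqs)
    model.log_mix_grid()

    D = _distance_matrix(model, enc)
    tree = nj_tree(D, msa.ids)
    all_labels = frozenset(msa.ids)
    main_splits = _bipartitions(tree, all_labels)

    rng = np.random.default_rng(seed)
    counts = {s: 0 for s in main_splits}
    for _ in range(n_bootstrap):
        cols = rng.integers(0, msa.n_cols, size=msa.n_cols)
        Db = _distance_matrix(model, enc, cols)
        bt = nj_tree(Db, msa.ids)
        for s in _bipartitions(bt, all_labels):
            if s in counts:
                counts[s] += 1
    supports = {s: 100.0 * c / n_bootstrap for s, c in counts.items()}

    rooted = False
    if outgroup:
        og = [o for o in outgroup if o in msa.ids]
        if og:
            if len(og) == len(msa.ids):
                raise ValueError("outgroup covers every leaf")
            mrca = tree.mrca(taxon_labels=og) if len(og) > 1 else tree.find_node_with_taxon_label(og[0])
            if mrca is tree.seed_node:
                # outgroup not monophyletic from the arbitrary NJ rooting:
                # root on the complement's MRCA edge instead
                ingroup = [l for l in msa.ids if l not in og]
                mrca = tree.mrca(taxon_labels=ingroup) if len(ingroup) > 1 else tree.find_node_with_taxon_label(ingroup[0])
            if mrca is not tree.seed_node and mrca.edge.length is not None:
                tree.reroot_at_edge(mrca.edge, length1=mrca.edge.length / 2.0,
                                    length2=mrca.edge.length / 2.0)
                rooted = True
        if not rooted:
            log.warning("outgroup %s absent from tree; returning unrooted tree", outgroup)
    if not rooted and midpoint_fallback:
        tree.reroot_at_midpoint()
        rooted = True

    # annotate internal nodes with supports
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        key = min(side, all_labels - side, key=lambda s: (len(s), tuple(sorted(s))))
        if key in supports:
            node.label = f"{supports[key]:.0f}"
    return PhyloTree(tree=tree, rooted=rooted, supports=supports, family=family)


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    support: float


def find_ortholog_pairs(
    ptree: PhyloTree,
    species_map: dict[str, str],
    focal: tuple[str, str] | None = None,
) -> list[OrthologPair]:
    """Sister-leaf orthologue pairs between the two focal species.

    A pair is emitted iff two leaves from different focal species form a
    two-leaf clade; the pair carries that node's bootstrap support.
    """
    if not ptree.rooted:
        raise ValueError("orthologue pairing requires a rooted tree")
    unmapped = [l for l in ptree.leaves() if l not in species_map]
    if unmapped:
        raise ValueError(f"leaves without species assignment: {unmapped[:5]}")
    if focal is None:
        focal_species = sorted({species_map[l] for l in ptree.leaves()})[:2]
    else:
        focal_species = list(focal)
    pairs = []
    for node in ptree.tree.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            la, lb = (k.taxon.label for k in kids)
            sa, sb = species_map[la], species_map[lb]
            if {sa, sb} == set(focal_species) and sa != sb:
                if sa != focal_species[0]:
                    la, lb = lb, la
                support = float(node.label) if node.label else float("nan")
                pairs.append(OrthologPair(gene_a=la, gene_b=lb, support=support))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


# --------------------------------------------------- simulation (for tests)


def simulate_jtt_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(20, size=length, p=JTT_FREQS / JTT_FREQS.sum())


def evolve_jtt(seq: np.ndarray, t: float, rng: np.random.Generator,
               model: JttModel | None = None) -> np.ndarray:
    model = model or JttModel()
    P = model.p_matrix(t)
    cum = np.cumsum(P[seq], axis=1)
    u = rng.random(len(seq))
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


def decode_aa(seq: np.ndarray) -> str:
    return "".join(AA[i] for i in seq)


def simulate_ortholog_family(
    n_ancestors: int = 8,
    t_paralog: float = 0.5,
    t_species: float = 0.05,
    length: int = 400,
    t_outgroup: float = 1.2,
    seed: int = 0,
    species: tuple[str, str] = ("spA", "spB"),
):
    """Speciation-then-divergence family: ancestral paralogs radiate from
    the family root, then each splits into one orthologue per species
    (species divergence much smaller than paralog divergence, as in a
    recent speciation). Returns (proteins, species_map, true_pairs,
    outgroup_id)."""
    rng = np.random.default_rng(seed)
    model = JttModel()
    root = simulate_jtt_sequence(length, rng)
    proteins: dict[str, str] = {}
    species_map: dict[str, str] = {}
    true_pairs = []
    for k in range(n_ancestors):
        anc = evolve_jtt(root, t_paralog, rng, model)
        a = evolve_jtt(anc, t_species, rng, model)
        b = evolve_jtt(anc, t_species, rng, model)
        ida, idb = f"{species[0]}_g{k + 1}", f"{species[1]}_g{k + 1}"
        proteins[ida] = decode_aa(a)
        proteins[idb] = decode_aa(b)
        species_map[ida] = species[0]
        species_map[idb] = species[1]
        true_pairs.append((ida, idb))
    out_id = "outgroup_1"
    proteins[out_id] = decode_aa(evolve_jtt(root, t_outgroup, rng, model))
    species_map[out_id] = "outgroup"
    return proteins, species_map, true_pairs, out_id
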