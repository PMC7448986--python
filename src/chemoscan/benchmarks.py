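"""Reproducible property benchmarks on forged data.

Each function regenerates its synthetic inputs from a seed, runs the
relevant pipeline stages, and measures recovery/error statistics. The
translated-search benchmark takes the scoring oracle as a callable so
that the reference implementation stays outside the measured code path.
"""

from __future__ import annotations

import numpy as np

from .codonmodel import CodonSimSpec, simulate_codon_pair
from .config import PipelineConfig
from .curate import FamilyDb, run_two_round
from .genomeforge import (
    default_benchmark_spec,
    forge_decoys,
    forge_genome,
    forge_transcripts,
    mutate_protein,
    rescue_scenario,
)
from .pipeline import evaluate_against_truth
from .phylo import (
    build_msa,
    build_tree,
    find_ortholog_pairs,
    nj_tree,
    simulate_ortholog_family,
)
from .seqs import CODON_TABLE
from .sitesel import alignment_from_pair, analyze_pair, fit_pair, lrt
from .sixframe import ScoringScheme, search, six_frame_translate
from .splicedmodel import spliced_align

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c, _a in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(_a, []).append(_c)

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(list(AA20), size=n))


def _back_translate(prot, rng):
    return "".join(_CODONS_BY_AA[a][rng.integers(len(_CODONS_BY_AA[a]))] for a in prot)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ------------------------------------------------- planted-gene recovery


def planted_gene_recovery(seeds=(1, 2, 3, 4, 5), config: PipelineConfig | None = None) -> dict:
    """Annotate the default forged benchmark genome for each seed and pool
    intact-gene sensitivity, precision, and pseudogene-status accuracy."""
    config = config or PipelineConfig()
    tp_intact = n_intact = matched_models = n_models = pseudo_ok = n_pseudo = 0
    for seed in seeds:
        genome, truth, refs = forge_genome(default_benchmark_spec(seed=seed))
        db = FamilyDb({"OR": refs}, decoys=forge_decoys(10, seed=seed + 900),
                      scoring=config.scoring)
        ann = run_two_round(genome, refs, config, family="OR", db=db)
        rep = evaluate_against_truth(ann, truth)
        n_int = len(truth.intact())
        tp_intact += round(rep.intact_sensitivity * n_int)
        n_intact += n_int
        n_models += rep.n_models
        matched_models += round((rep.precision or 0.0) * rep.n_models)
        n_ps = sum(1 for r in truth if r.status in ("pseudo_stop", "pseudo_frameshift"))
        pseudo_ok += round((rep.pseudogene_status_accuracy or 0.0) * n_ps)
        n_pseudo += n_ps
    return {
        "sensitivity": tp_intact / n_intact,
        "precision": matched_models / n_models if n_models else None,
        "pseudogene_status_accuracy": pseudo_ok / n_pseudo,
        "n_seeds": len(seeds),
    }


def round2_rescue(seed: int = 1, config: PipelineConfig | None = None) -> dict:
    """Whether the hidden short-exon paralog is absent after round 1 and
    present after round 2."""
    config = config or PipelineConfig()
    genome, truth, refs, meta = rescue_scenario(seed=seed)
    ann = run_two_round(genome, refs, config, family="OR")
    hidden = next(r for r in truth if r.gene_id == meta["hidden_gene"])

    def covered(annset):
        for m in annset.models:
            span = (min(s for s, _ in m.exons), max(e for _, e in m.exons))
            ov = max(0, min(span[1], hidden.span[1]) - max(span[0], hidden.span[0]))
            if m.scaffold_id == hidden.scaffold and ov > 0.5 * (hidden.span[1] - hidden.span[0]):
                return True
        return False

    return {"round1_present": covered(ann.round1), "round2_present": covered(ann)}


# --------------------------------------------------- spliced exactness


def spliced_exactness(n_loci: int = 50, seed: int = 0) -> dict:
    """Construct loci with known GT..AG intron structure and measure exact
    exon-boundary recovery; intronless perfect matches are checked for
    exact recovery as well."""
    rng = np.random.default_rng(seed)
    exact = 0
    intronless_exact = 0
    n_intronless = 0
    for k in range(n_loci):
        n_codons = int(rng.integers(200, 400))
        prot = "M" + _random_protein(rng, n_codons - 1)
        cds = _back_translate(prot, rng)
        n_introns = int(rng.integers(0, 5))
        sites = sorted(rng.choice(np.arange(15, n_codons - 15), size=n_introns, replace=False)) if n_introns else []
        sites = [s for i, s in enumerate(sites) if i == 0 or s - sites[i - 1] >= 15]
        parts, prev = [], 0
        true_exons = []
        pos = 300
        for c in sites:
            seg = cds[3 * prev : 3 * c]
            parts.append(seg)
            true_exons.append((pos, pos + len(seg)))
            pos += len(seg)
            ilen = int(rng.integers(60, 400))
            parts.append("GT" + _random_dna(rng, ilen - 4) + "AG")
            pos += ilen
            prev = c
        seg = cds[3 * prev :]
        parts.append(seg)
        true_exons.append((pos, pos + len(seg)))
        dna = _random_dna(rng, 300) + "".join(parts) + _random_dna(rng, 300)
        model = spliced_align(prot, dna, "+")
        if model.exons == true_exons:
            exact += 1
            if not sites:
                intronless_exact += 1
        if not sites:
            n_intronless += 1
    return {
        "exact_fraction": exact / n_loci,
        "n_intronless": n_intronless,
        "intronless_exact_fraction": (intronless_exact / n_intronless) if n_intronless else 1.0,
    }


# ------------------------------------------------------- search oracle


def search_oracle_agreement(oracle, n_instances: int = 200, seed: int = 0) -> dict:
    """Fraction of random small instances where the seeded translated
    search reproduces the exhaustive Smith-Waterman ``oracle`` score.

    ``oracle(query, frame_protein, scoring) -> score`` must be an
    independent local-alignment implementation.
    """
    rng = np.random.default_rng(seed)
    scoring = ScoringScheme()
    agree = 0
    for _ in range(n_instances):
        qlen = int(rng.integers(12, 61))
        prot = _random_protein(rng, qlen)
        embed = _back_translate(prot[: max(10, qlen // 2)], rng)
        dna = (_random_dna(rng, int(rng.integers(50, 200))) + embed + _random_dna(rng, 100))[:400]
        hits = search(prot, {"s": dna}, scoring, evalue_cutoff=float("inf"), query_id="q")
        mine = max((h.raw_score for h in hits), default=0.0)
        ref = max(
            oracle(prot, fr.protein, scoring)
            for fr in six_frame_translate(dna)
            if fr.protein
        )
        agree += int(abs(mine - ref) < 1e-9)
    return {"agreement": agree / n_instances, "n": n_instances}


# ------------------------------------------------------- completeness


def completeness_accounting(seed: int = 1, config: PipelineConfig | None = None) -> dict:
    """Forge transcripts including 3 genome-absent genes; count missing
    and check the 120/190-aa boundary behaviour (119/120, 189/190)."""
    from .curate import completeness_check

    config = config or PipelineConfig()
    spec = default_benchmark_spec(seed=seed)
    spec.n_genes = 12
    spec.n_pseudo_stop = 1
    spec.n_pseudo_frameshift = 1
    spec.n_partial = 1
    spec.tandem_cluster_sizes = ()
    spec.scaffold_count = 3
    genome, truth, refs = forge_genome(spec)
    ann = run_two_round(genome, refs, config, family="OR")
    rng = np.random.default_rng(seed + 5)
    extras = {
        f"ABS{i}": mutate_protein(refs[list(refs)[i]], 0.1, rng) for i in range(3)
    }
    tr = forge_transcripts(truth, extra_genes=extras, seed=seed + 6)
    rep = completeness_check(tr, refs, ann, config=config)

    rid = list(refs)[0]
    t119 = completeness_check({"t": _back_translate(refs[rid][:119], rng)}, refs, ann,
                              threshold_aa=120, config=config)
    t120 = completeness_check({"t": _back_translate(refs[rid][:120], rng)}, refs, ann,
                              threshold_aa=120, config=config)
    t189 = completeness_check({"t": _back_translate(refs[rid][:189], rng)}, refs, ann,
                              threshold_aa=190, config=config)
    t190 = completeness_check({"t": _back_translate(refs[rid][:190], rng)}, refs, ann,
                              threshold_aa=190, config=config)
    return {
        "transcripts_missing": rep.transcripts_missing,
        "transcripts_total": rep.transcripts_total,
        "boundary_119_counted": t119.transcripts_total,
        "boundary_120_counted": t120.transcripts_total,
        "boundary_189_counted": t189.transcripts_total,
        "boundary_190_counted": t190.transcripts_total,
    }


# ------------------------------------------------------ trees and pairs


def _random_additive_matrix(n, rng):
    """A random binary tree with branch lengths and its additive matrix."""
    import dendropy

    taxa = [f"t{i}" for i in range(n)]
    parts = list(taxa)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0, size=2)
        merged = f"({parts[i]}:{bi:.6f},{parts[j]}:{bj:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (int(i), int(j))] + [merged]
    tree = dendropy.Tree.get(data=parts[0] + ";", schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tx = {x.label: x for x in tree.taxon_namespace}
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                D[a, b] = pdm.distance(tx[taxa[a]], tx[taxa[b]])
    return tree, D, taxa


def nj_additive_exactness(n_matrices: int = 100, seed: int = 0) -> dict:
    """NJ must recover the generating topology of additive matrices."""
    import dendropy
    from dendropy.calculate import treecompare

    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_matrices):
        n = int(rng.integers(4, 13))
        true_tree, D, taxa = _random_additive_matrix(n, rng)
        est = nj_tree(D, taxa)
        tns = dendropy.TaxonNamespace()
        a = dendropy.Tree.get(data=true_tree.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        b = dendropy.Tree.get(data=est.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        a.encode_bipartitions()
        b.encode_bipartitions()
        exact += int(treecompare.symmetric_difference(a, b) == 0)
    return {"exact_fraction": exact / n_matrices, "n": n_matrices}


def ortholog_pair_recovery(n_families: int = 20, seed: int = 0, n_bootstrap: int = 50) -> dict:
    """Planted speciation-then-divergence families: fraction of families
    whose 1:1 pairs are all recovered, plus overall pair recall."""
    fam_ok = 0
    pair_tp = pair_total = 0
    for k in range(n_families):
        prots, smap, pairs, og = simulate_ortholog_family(seed=seed + k)
        msa = build_msa(prots)
        pt = build_tree(msa, "IR", n_bootstrap=n_bootstrap, seed=seed + k, outgroup=[og])
        got = {(p.gene_a, p.gene_b) for p in find_ortholog_pairs(pt, smap, focal=("spA", "spB"))}
        want = set(pairs)
        fam_ok += int(got == want)
        pair_tp += len(got & want)
        pair_total += len(want)
    return {
        "family_recovery": fam_ok / n_families,
        "pair_recall": pair_tp / pair_total,
        "n_families": n_families,
    }


def bootstrap_determinism(seed: int = 0, n_bootstrap: int = 200) -> bool:
    prots, smap, pairs, og = simulate_ortholog_family(n_ancestors=5, seed=seed)
    msa = build_msa(prots)
    t1 = build_tree(msa, "IR", n_bootstrap=n_bootstrap, seed=seed, outgroup=[og])
    t2 = build_tree(msa, "IR", n_bootstrap=n_bootstrap, seed=seed, outgroup=[og])
    return t1.supports == t2.supports


# -------------------------------------------------------- site models


def lrt_null_fpr(n_reps: int = 60, seed: int = 0, n_codons: int = 300,
                 alpha: float = 0.01) -> dict:
    """False-positive rate of the M7-vs-M8 LRT on M7-simulated pairs."""
    fp = 0
    for rep in range(n_reps):
        (a, b), _ = simulate_codon_pair(
            CodonSimSpec(model="M7", n_codons=n_codons, t=0.5, kappa=2.0,
                         rng_seed=seed * 100_003 + rep)
        )
        aln = alignment_from_pair(a, b)
        m7, m8 = fit_pair(aln, n_restarts=1, seed=rep)
        _, p = lrt(m7, m8)
        fp += int(p < alpha)
    return {"fpr": fp / n_reps, "n": n_reps}


def m8_power_and_recovery(n_power: int = 12, n_recovery: int = 20, seed: int = 0) -> dict:
    """Power of the full decision rule on M8-simulated pairs (n=300) and
    parameter recovery at n=500 codons."""
    flagged = 0
    for rep in range(n_power):
        (a, b), _ = simulate_codon_pair(
            CodonSimSpec(model="M8", n_codons=300, t=0.5, kappa=2.0, p0=0.5,
                         omega_s=2.0, rng_seed=seed * 100_003 + rep)
        )
        aln = alignment_from_pair(a, b)
        res = analyze_pair(aln, n_restarts=1, seed=rep)
        flagged += int(res.positively_selected)
    omegas, p0s = [], []
    for rep in range(n_recovery):
        (a, b), _ = simulate_codon_pair(
            CodonSimSpec(model="M8", n_codons=500, t=0.5, kappa=2.0, p0=0.5,
                         omega_s=2.0, rng_seed=seed * 200_003 + rep)
        )
        aln = alignment_from_pair(a, b)
        _, m8 = fit_pair(aln, n_restarts=5, seed=rep)
        omegas.append(m8.omega_s)
        p0s.append(m8.p0)
    return {
        "power": flagged / n_power,
        "median_omega_s": float(np.median(omegas)),
        "median_p0": float(np.median(p0s)),
        "n_power": n_power,
        "n_recovery": n_recovery,
    }
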