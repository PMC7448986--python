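"""Synthetic genomes with planted receptor-like gene families.

The forge generates multi-scaffold genomes carrying multi-exon genes
with canonical GT..AG introns, tandem duplicate clusters with low
divergence, stop-codon and frameshift pseudogenes, truncated partial
genes, diverged "outgroup" reference proteins, spliced transcript sets
(optionally containing genes absent from the genome), and decoy
proteins — i.e. every feature the annotation pipeline has to cope with,
each recorded in a truth set for later evaluation.

Intergenic background is i.i.d. uniform nucleotides (GC 50%) so that no
accidental homology arises. Reference proteins are made by random
amino-acid substitutions (default 15%) on the planted proteins,
emulating cross-species queries. Frameshift pseudogenes carry a 1-bp
deletion; stop pseudogenes have one sense codon mutated to TAA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codonmodel import CodonSimSpec, simulate_codon_pair  # noqa: F401  (re-export)
from .seqs import CODON_TABLE, revcomp, translate

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS_BY_AA: dict[str, list[str]] = {}
for _c, _a in sorted(CODON_TABLE.items()):
    _CODONS_BY_AA.setdefault(_a, []).append(_c)

MIN_EXON_CODONS = 10
GENE_MARGIN = 800  # bp kept free around every planted gene


@dataclass
class FamilySpec:
    """Conditions of one forged gene family."""

    family_name: str = "OR"
    n_genes: int = 60
    intron_count_range: tuple[int, int] = (2, 6)
    intron_length_range: tuple[int, int] = (60, 400)
    protein_length_range: tuple[int, int] = (380, 460)
    n_pseudo_stop: int = 6
    n_pseudo_frameshift: int = 4
    n_partial: int = 5
    tandem_cluster_sizes: tuple[int, ...] = (4, 4)
    within_cluster_divergence: float = 0.05  # nt substitutions/site
    scaffold_count: int = 10
    scaffold_length: int = 200_000
    ref_divergence: float = 0.15  # aa substitutions/site, planted -> reference
    derived_divergence: float = 0.08  # nt, parent -> pseudo/partial copy
    partial_fraction: tuple[float, float] = (0.55, 0.70)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_pseudo_stop + self.n_pseudo_frameshift + self.n_partial > self.n_genes:
            raise ValueError("defective gene counts exceed n_genes")
        for rng_ in (self.intron_count_range, self.intron_length_range, self.protein_length_range):
            if rng_[0] > rng_[1]:
                raise ValueError(f"empty range {rng_}")
        if sum(self.tandem_cluster_sizes) > self.n_intact:
            raise ValueError("tandem clusters larger than the intact gene count")

    @property
    def n_intact(self) -> int:
        return self.n_genes - self.n_pseudo_stop - self.n_pseudo_frameshift - self.n_partial


def default_benchmark_spec(seed: int = 1, family: str = "OR") -> FamilySpec:
    """The standard 2-Mb benchmark genome: 60 genes, 6 stop-pseudogenes,
    4 frameshift-pseudogenes, 5 partials, two 4-gene tandem clusters."""
    return FamilySpec(family_name=family, rng_seed=seed)


@dataclass
class TruthRecord:
    gene_id: str
    family: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # forward-strand bp, coding (5'->3') order
    status: str  # intact | pseudo_stop | pseudo_frameshift | partial
    protein: str
    cds: str  # concatenated exon sequence, coding strand
    source_ref_id: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        lo = min(s for s, _ in self.exons)
        hi = max(e for _, e in self.exons)
        return lo, hi


@dataclass
class TruthSet:
    records: list[TruthRecord] = field(default_factory=list)

    def intact(self) -> list[TruthRecord]:
        return [r for r in self.records if r.status == "intact"]

    def by_status(self, status: str) -> list[TruthRecord]:
        return [r for r in self.records if r.status == status]

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# ---------------------------------------------------------------- helpers


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def back_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS_BY_AA[a][rng.integers(len(_CODONS_BY_AA[a]))] for a in protein)


def mutate_protein(protein: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute ``divergence`` of the residues with random different aa."""
    n_mut = int(round(divergence * len(protein)))
    pos = rng.choice(len(protein), size=min(n_mut, len(protein)), replace=False)
    chars = list(protein)
    for p in pos:
        choices = [a for a in AA20 if a != chars[p]]
        chars[p] = choices[rng.integers(len(choices))]
    return "".join(chars)


def mutate_cds(cds: str, divergence: float, rng: np.random.Generator) -> str:
    """Nucleotide substitutions avoiding the creation of internal stops."""
    n_mut = int(round(divergence * len(cds)))
    pos = rng.choice(len(cds), size=min(n_mut, len(cds)), replace=False)
    chars = list(cds)
    for p in sorted(pos):
        old = chars[p]
        choices = [b for b in "ACGT" if b != old]
        for b in rng.permutation(choices):
            chars[p] = b
            c0 = 3 * (p // 3)
            if CODON_TABLE["".join(chars[c0 : c0 + 3])] != "*":
                break
        else:
            chars[p] = old
    return "".join(chars)


@dataclass
class _GeneBuild:
    """A gene laid out on its coding strand before placement."""

    gene_id: str
    protein: str
    cds: str
    exons_local: list[tuple[int, int]]  # coding-strand coords within gene_seq
    gene_seq: str
    status: str
    source_ref_id: str | None = None


def _layout_gene(
    gene_id: str,
    cds: str,
    rng: np.random.Generator,
    spec: FamilySpec,
    intron_positions: list[int] | None = None,
    status: str = "intact",
) -> _GeneBuild:
    """Split a CDS by introns at codon boundaries and assemble the gene."""
    n_codons = len(cds) // 3
    if intron_positions is None:
        lo, hi = spec.intron_count_range
        k = int(rng.integers(lo, hi + 1))
        k = min(k, max(0, n_codons // MIN_EXON_CODONS - 1))
        sites: list[int] = []
        tries = 0
        while len(sites) < k and tries < 500:
            c = int(rng.integers(MIN_EXON_CODONS, n_codons - MIN_EXON_CODONS + 1))
            if all(abs(c - s) >= MIN_EXON_CODONS for s in sites):
                sites.append(c)
            tries += 1
        intron_positions = sorted(sites)
    parts = []
    exons_local = []
    pos = 0
    prev = 0
    for c in intron_positions:
        exon = cds[3 * prev : 3 * c]
        parts.append(exon)
        exons_local.append((pos, pos + len(exon)))
        pos += len(exon)
        ilen = int(rng.integers(spec.intron_length_range[0], spec.intron_length_range[1] + 1))
        interior = "".join(rng.choice(list("ACGT"), size=max(ilen - 4, 1)))
        intron = "GT" + interior + "AG"
        parts.append(intron)
        pos += len(intron)
        prev = c
    exon = cds[3 * prev :]
    parts.append(exon)
    exons_local.append((pos, pos + len(exon)))
    pos += len(exon)
    parts.append("TAA")  # terminal stop, outside the CDS
    return _GeneBuild(
        gene_id=gene_id,
        protein=translate(cds),
        cds=cds,
        exons_local=exons_local,
        gene_seq="".join(parts),
        status=status,
    )


def _apply_stop(build: _GeneBuild, rng: np.random.Generator) -> _GeneBuild:
    """Mutate one internal sense codon of the CDS to TAA (in place in gene_seq)."""
    n_codons = len(build.cds) // 3
    c = int(rng.integers(max(1, n_codons // 10), max(2, 9 * n_codons // 10)))
    new_cds = build.cds[:3 * c] + "TAA" + build.cds[3 * c + 3 :]
    # rebuild gene_seq with the same exon layout
    seq = list(build.gene_seq)
    offset = 0
    for (es, ee), cds_start in zip(build.exons_local, _cds_offsets(build)):
        if cds_start <= 3 * c < cds_start + (ee - es):
            k = es + (3 * c - cds_start)
            seq[k : k + 3] = "TAA"
            break
        offset += ee - es
    protein = translate(new_cds).replace("*", "X")
    return _GeneBuild(
        build.gene_id, protein, new_cds, build.exons_local, "".join(seq), "pseudo_stop",
        build.source_ref_id,
    )


def _cds_offsets(build: _GeneBuild) -> list[int]:
    out, acc = [], 0
    for es, ee in build.exons_local:
        out.append(acc)
        acc += ee - es
    return out


def _apply_frameshift(build: _GeneBuild, rng: np.random.Generator) -> _GeneBuild:
    """Delete 1 bp in the middle of the largest exon."""
    ei = max(range(len(build.exons_local)), key=lambda i: build.exons_local[i][1] - build.exons_local[i][0])
    es, ee = build.exons_local[ei]
    k = int(rng.integers(es + (ee - es) // 3, es + 2 * (ee - es) // 3))
    seq = build.gene_seq[:k] + build.gene_seq[k + 1 :]
    exons = []
    for s, e in build.exons_local:
        s2 = s - 1 if s > k else s
        e2 = e - 1 if e > k else e
        exons.append((s2, e2))
    cds_off = _cds_offsets(build)[ei]
    cds_pos = cds_off + (k - es)
    new_cds = build.cds[:cds_pos] + build.cds[cds_pos + 1 :]
    return _GeneBuild(
        build.gene_id, build.protein, new_cds, exons, seq, "pseudo_frameshift",
        build.source_ref_id,
    )


def _truncate(build: _GeneBuild, rng: np.random.Generator, frac_range) -> _GeneBuild:
    """Keep only the 5' fraction of the gene (a partial model)."""
    frac = rng.uniform(*frac_range)
    n_codons = len(build.cds) // 3
    keep = max(MIN_EXON_CODONS, int(frac * n_codons))
    cds = build.cds[: 3 * keep]
    # exon layout restricted to kept CDS
    exons = []
    parts = []
    pos = 0
    consumed = 0
    for (es, ee), off in zip(build.exons_local, _cds_offsets(build)):
        if off >= 3 * keep:
            break
        length = min(ee - es, 3 * keep - off)
        seg = build.gene_seq[es : es + length]
        if exons:
            intron = build.gene_seq[prev_end:es]  # noqa: F821
            parts.append(intron)
            pos += len(intron)
        parts.append(seg)
        exons.append((pos, pos + length))
        pos += length
        consumed += length
        prev_end = ee
    return _GeneBuild(
        build.gene_id, translate(cds), cds, exons, "".join(parts), "partial",
        build.source_ref_id,
    )


# ---------------------------------------------------------------- forge


def forge_genome(spec: FamilySpec):
    """Build (genome, truth, refs) for one family.

    ``genome`` maps scaffold id to sequence; ``truth`` is the planted
    annotation; ``refs`` maps reference-protein id to sequence (diverged
    outgroup copies of the intact planted proteins).
    """
    rng = np.random.default_rng(spec.rng_seed)
    fam = spec.family_name
    builds: list[_GeneBuild] = []
    clusters: list[list[_GeneBuild]] = []

    n_cluster_genes = sum(spec.tandem_cluster_sizes)
    n_solo = spec.n_intact - n_cluster_genes
    gid = 0

    def next_id():
        nonlocal gid
        gid += 1
        return f"{fam}_g{gid:03d}"

    solo_builds = []
    for _ in range(n_solo):
        L = int(rng.integers(*spec.protein_length_range))
        prot = random_protein(rng, L)
        b = _layout_gene(next_id(), back_translate(prot, rng), rng, spec)
        solo_builds.append(b)
        builds.append(b)

    for size in spec.tandem_cluster_sizes:
        L = int(rng.integers(*spec.protein_length_range))
        founder_prot = random_protein(rng, L)
        founder = _layout_gene(next_id(), back_translate(founder_prot, rng), rng, spec)
        members = [founder]
        n_codons = len(founder.cds) // 3
        founder_introns = _intron_sites(founder)
        for _ in range(size - 1):
            cds = mutate_cds(founder.cds, spec.within_cluster_divergence, rng)
            m = _layout_gene(next_id(), cds, rng, spec, intron_positions=founder_introns)
            members.append(m)
        clusters.append(members)
        builds.extend(members)

    intact_pool = [b for b in builds]
    derived = []
    for status, count in (
        ("pseudo_stop", spec.n_pseudo_stop),
        ("pseudo_frameshift", spec.n_pseudo_frameshift),
        ("partial", spec.n_partial),
    ):
        for _ in range(count):
            parent = intact_pool[int(rng.integers(len(intact_pool)))]
            cds = mutate_cds(parent.cds, spec.derived_divergence, rng)
            b = _layout_gene(next_id(), cds, rng, spec)
            b.source_ref_id = f"REF_{parent.gene_id}"
            if status == "pseudo_stop":
                b = _apply_stop(b, rng)
            elif status == "pseudo_frameshift":
                b = _apply_frameshift(b, rng)
            else:
                b = _truncate(b, rng, spec.partial_fraction)
            derived.append(b)
    builds.extend(derived)

    # ---- references: diverged outgroup copies of intact proteins
    refs: dict[str, str] = {}
    for b in intact_pool:
        refs[f"REF_{b.gene_id}"] = mutate_protein(b.protein, spec.ref_divergence, rng)
        b.source_ref_id = f"REF_{b.gene_id}"

    # ---- sizing check
    total_gene_bp = sum(len(b.gene_seq) + 2 * GENE_MARGIN for b in builds)
    capacity = spec.scaffold_count * spec.scaffold_length
    if total_gene_bp > 0.8 * capacity:
        raise ValueError(
            f"family needs ~{total_gene_bp} bp but scaffolds provide {capacity} bp; "
            "increase scaffold_count/scaffold_length or reduce n_genes"
        )

    # ---- placement
    scaffolds = [f"scf_{i + 1:02d}" for i in range(spec.scaffold_count)]
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    placements: list[tuple[_GeneBuild, str, str, int]] = []  # build, scaffold, strand, pos

    def try_place(length: int, scaffold=None, near=None):
        for _ in range(200):
            sc = scaffold if scaffold else scaffolds[int(rng.integers(len(scaffolds)))]
            max_start = spec.scaffold_length - length - GENE_MARGIN
            if max_start <= GENE_MARGIN:
                continue
            if near is not None:
                start = near
                if start > max_start:
                    return None
            else:
                start = int(rng.integers(GENE_MARGIN, max_start))
            iv = (start - GENE_MARGIN, start + length + GENE_MARGIN)
            if all(e <= iv[0] or s >= iv[1] for s, e in occupied[sc]):
                occupied[sc].append(iv)
                return sc, start
            if near is not None:
                return None
        return None

    cluster_members = {id(m) for cl in clusters for m in cl}
    for cl in clusters:
        strand = "+" if rng.random() < 0.5 else "-"
        total = sum(len(m.gene_seq) for m in cl) + 3000 * len(cl)
        placed = None
        for _ in range(100):
            sc = scaffolds[int(rng.integers(len(scaffolds)))]
            start0 = int(rng.integers(GENE_MARGIN, max(GENE_MARGIN + 1, spec.scaffold_length - total - GENE_MARGIN)))
            pos = start0
            ok = []
            good = True
            for m in cl:
                res = try_place(len(m.gene_seq), scaffold=sc, near=pos)
                if res is None:
                    good = False
                    break
                ok.append((m, sc, strand, res[1]))
                pos = res[1] + len(m.gene_seq) + int(rng.integers(1000, 3000))
            if good:
                placed = ok
                break
            for m, s_, st_, p_ in ok:  # roll back partial cluster placement
                occupied[s_].remove((p_ - GENE_MARGIN, p_ + len(m.gene_seq) + GENE_MARGIN))
        if placed is None:
            raise ValueError("could not place tandem cluster; scaffolds too crowded")
        placements.extend(placed)

    for b in builds:
        if id(b) in cluster_members:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        res = try_place(len(b.gene_seq))
        if res is None:
            raise ValueError(f"could not place gene {b.gene_id}; scaffolds too crowded")
        placements.append((b, res[0], strand, res[1]))

    # ---- genome assembly
    genome_arr = {s: rng.choice(list("ACGT"), size=spec.scaffold_length) for s in scaffolds}
    records = []
    for b, sc, strand, start in placements:
        seq = b.gene_seq if strand == "+" else revcomp(b.gene_seq)
        genome_arr[sc][start : start + len(seq)] = list(seq)
        glen = len(b.gene_seq)
        exons = []
        for s_, e_ in b.exons_local:
            if strand == "+":
                exons.append((start + s_, start + e_))
            else:
                exons.append((start + glen - e_, start + glen - s_))
        records.append(
            TruthRecord(
                gene_id=b.gene_id,
                family=fam,
                scaffold=sc,
                strand=strand,
                exons=exons,
                status=b.status,
                protein=b.protein,
                cds=b.cds,
                source_ref_id=b.source_ref_id,
            )
        )
    genome = {s: "".join(a) for s, a in genome_arr.items()}
    records.sort(key=lambda r: (r.scaffold, r.span))
    return genome, TruthSet(records), refs


def _intron_sites(build: _GeneBuild) -> list[int]:
    sites = []
    acc = 0
    for es, ee in build.exons_local[:-1]:
        acc += (ee - es) // 3
        sites.append(acc)
    return sites


def forge_transcripts(
    truth: TruthSet,
    extra_genes: dict[str, str] | None = None,
    seed: int = 0,
    truncation: tuple[int, int] = (0, 30),
    subset: list[str] | None = None,
) -> dict[str, str]:
    """Spliced transcripts for intact genes, plus genome-absent extras.

    Each selected intact gene yields one transcript: its concatenated
    exons with small random end truncations. ``extra_genes`` (protein
    id -> sequence) are back-translated into transcripts with no
    counterpart in the genome, emulating genes missing from the assembly.
    """
    if not len(truth):
        raise ValueError("truth set is empty")
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for rec in truth.intact():
        if subset is not None and rec.gene_id not in subset:
            continue
        lo = int(rng.integers(truncation[0], truncation[1] + 1)) if truncation[1] else 0
        hi = int(rng.integers(truncation[0], truncation[1] + 1)) if truncation[1] else 0
        seq = rec.cds[lo : len(rec.cds) - hi]
        out[f"TR_{rec.gene_id}"] = seq
    for gid_, prot in (extra_genes or {}).items():
        out[f"TR_extra_{gid_}"] = back_translate(prot.rstrip("*"), rng)
    return out


def forge_decoys(n: int, seed: int = 0, length_range=(300, 500)) -> dict[str, str]:
    """Random non-homologous proteins for the family-consistency check."""
    rng = np.random.default_rng(seed)
    return {
        f"DECOY_{i + 1:02d}": random_protein(rng, int(rng.integers(*length_range)))
        for i in range(n)
    }


def forge_species_pair(
    spec: FamilySpec,
    species_divergence: float = 0.04,
    species: tuple[str, str] = ("spA", "spB"),
):
    """Two divergence-separated genomes carrying orthologous copies of
    the same planted family.

    Species A is forged from ``spec``; species B carries, for every
    planted gene, a copy whose CDS diverged by ``species_divergence``
    (nt substitutions/site) placed independently on B's own scaffolds.
    References are shared (the outgroup copies from species A's forge).
    Returns (genomes, truths, refs, ortholog_truth) where genomes and
    truths are per-species dicts and ortholog_truth maps gene id in A to
    the orthologous gene id in B.
    """
    genome_a, truth_a, refs = forge_genome(spec)
    rng = np.random.default_rng(spec.rng_seed + 10_007)
    spec_b = FamilySpec(**{**spec.__dict__, "rng_seed": spec.rng_seed + 1})
    scaffolds = [f"scf_{i + 1:02d}" for i in range(spec.scaffold_count)]
    occupied = {s: [] for s in scaffolds}
    genome_arr = {s: rng.choice(list("ACGT"), size=spec.scaffold_length) for s in scaffolds}
    records = []
    ortho = {}
    for rec in truth_a:
        if rec.status in ("pseudo_stop", "pseudo_frameshift"):
            continue  # pseudogenisation treated as lineage-specific
        cds = mutate_cds(rec.cds, species_divergence, rng)
        build = _layout_gene(rec.gene_id + "b", cds, rng, spec_b, status=rec.status)
        build.source_ref_id = rec.source_ref_id
        strand = "+" if rng.random() < 0.5 else "-"
        placed = None
        for _ in range(300):
            sc = scaffolds[int(rng.integers(len(scaffolds)))]
            max_start = spec.scaffold_length - len(build.gene_seq) - GENE_MARGIN
            if max_start <= GENE_MARGIN:
                continue
            start = int(rng.integers(GENE_MARGIN, max_start))
            iv = (start - GENE_MARGIN, start + len(build.gene_seq) + GENE_MARGIN)
            if all(e <= iv[0] or s_ >= iv[1] for s_, e in occupied[sc]):
                occupied[sc].append(iv)
                placed = (sc, start)
                break
        if placed is None:
            raise ValueError("could not place orthologous copy; scaffolds too crowded")
        sc, start = placed
        seq = build.gene_seq if strand == "+" else revcomp(build.gene_seq)
        genome_arr[sc][start : start + len(seq)] = list(seq)
        glen = len(build.gene_seq)
        exons = []
        for s_, e_ in build.exons_local:
            if strand == "+":
                exons.append((start + s_, start + e_))
            else:
                exons.append((start + glen - e_, start + glen - s_))
        records.append(
            TruthRecord(
                gene_id=build.gene_id,
                family=spec.family_name,
                scaffold=sc,
                strand=strand,
                exons=exons,
                status=build.status,
                protein=build.protein,
                cds=build.cds,
                source_ref_id=build.source_ref_id,
            )
        )
        ortho[rec.gene_id] = build.gene_id
    genome_b = {s: "".join(a) for s, a in genome_arr.items()}
    records.sort(key=lambda r: (r.scaffold, r.span))
    genomes = {species[0]: genome_a, species[1]: genome_b}
    truths = {species[0]: truth_a, species[1]: TruthSet(records)}
    return genomes, truths, refs, ortho


def rescue_scenario(
    seed: int = 1,
    ref_divergence: float = 0.50,
    paralog_divergence: float = 0.22,
    scaffold_length: int = 100_000,
    family: str = "OR",
):
    """A two-paralog family in which one gene is detectable only via the
    other: gene A has long exons and a usable (if diverged) reference;
    its paralog B has short exons and, through the combined divergence,
    falls below search significance against that reference — until round
    2 adds A's own annotated protein as a query.

    Returns (genome, truth, refs, meta) with meta naming the hidden gene.
    """
    rng = np.random.default_rng(seed)
    spec = FamilySpec(
        family_name=family,
        n_genes=2,
        n_pseudo_stop=0,
        n_pseudo_frameshift=0,
        n_partial=0,
        tandem_cluster_sizes=(),
        scaffold_count=1,
        scaffold_length=scaffold_length,
        intron_count_range=(2, 2),
        intron_length_range=(60, 90),
        protein_length_range=(420, 440),
        rng_seed=seed,
    )
    prot_a = random_protein(rng, 430)
    cds_a = back_translate(prot_a, rng)
    build_a = _layout_gene(f"{family}_A", cds_a, rng, spec)

    prot_b_full = mutate_protein(prot_a, paralog_divergence, rng)
    prot_b = prot_b_full[:240]
    cds_b = back_translate(prot_b, rng)
    spec_b = FamilySpec(
        family_name=family,
        n_genes=1,
        n_pseudo_stop=0,
        n_pseudo_frameshift=0,
        n_partial=0,
        tandem_cluster_sizes=(),
        scaffold_count=1,
        scaffold_length=scaffold_length,
        intron_count_range=(9, 9),
        intron_length_range=(60, 90),
        protein_length_range=(240, 240),
        rng_seed=seed + 1,
    )
    sites = list(range(24, 240 - 23, 24))[:9]
    build_b = _layout_gene(f"{family}_B", cds_b, rng, spec_b, intron_positions=sites)

    refs = {f"REF_{family}_A": mutate_protein(prot_a, ref_divergence, rng)}

    sc = "scf_01"
    seq = rng.choice(list("ACGT"), size=scaffold_length)
    pos_a, pos_b = 20_000, 60_000
    records = []
    for build, pos in ((build_a, pos_a), (build_b, pos_b)):
        seq[pos : pos + len(build.gene_seq)] = list(build.gene_seq)
        exons = [(pos + s, pos + e) for s, e in build.exons_local]
        records.append(
            TruthRecord(
                gene_id=build.gene_id,
                family=family,
                scaffold=sc,
                strand="+",
                exons=exons,
                status="intact",
                protein=build.protein,
                cds=build.cds,
                source_ref_id=f"REF_{family}_A",
            )
        )
    genome = {sc: "".join(seq)}
    meta = {"hidden_gene": f"{family}_B", "visible_gene": f"{family}_A"}
    return genome, TruthSet(records), refs, meta
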