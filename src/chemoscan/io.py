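"""Standard-format readers/writers.

Internal coordinates are 0-based half-open on the forward strand; GFF3
output is 1-based closed, per the format. FASTA goes through Biopython.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .curate import AnnotationSet, CompletenessReport
from .genomeforge import TruthSet
from .splicedmodel import GeneModel


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_truth_gff3(truth: TruthSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in truth:
            lo, hi = rec.span
            fh.write(
                f"{rec.scaffold}\tforge\tgene\t{lo + 1}\t{hi}\t.\t{rec.strand}\t.\t"
                f"ID={rec.gene_id};family={rec.family};status={rec.status}\n"
            )
            for k, (s, e) in enumerate(sorted(rec.exons)):
                fh.write(
                    f"{rec.scaffold}\tforge\texon\t{s + 1}\t{e}\t.\t{rec.strand}\t.\t"
                    f"ID={rec.gene_id}.e{k + 1};Parent={rec.gene_id}\n"
                )


def write_models_gff3(models: list[GeneModel], path, source: str = "chemoscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in sorted(models, key=lambda x: (x.scaffold_id, min(s for s, _ in x.exons))):
            lo = min(s for s, _ in m.exons)
            hi = max(e for _, e in m.exons)
            attrs = (
                f"ID={m.gene_id};family={m.family};status={m.status};"
                f"frameshifts={m.frameshift_events};internal_stops={m.internal_stop_count};"
                f"reference={m.reference_id}"
            )
            fh.write(f"{m.scaffold_id}\t{source}\tgene\t{lo + 1}\t{hi}\t"
                     f"{m.model_score:.0f}\t{m.strand}\t.\t{attrs}\n")
            fh.write(f"{m.scaffold_id}\t{source}\tmRNA\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t"
                     f"ID={m.gene_id}.t1;Parent={m.gene_id}\n")
            for k, (s, e) in enumerate(sorted(m.exons)):
                fh.write(f"{m.scaffold_id}\t{source}\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                         f"ID={m.gene_id}.e{k + 1};Parent={m.gene_id}.t1\n")
                fh.write(f"{m.scaffold_id}\t{source}\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                         f"ID={m.gene_id}.c{k + 1};Parent={m.gene_id}.t1\n")


def write_counts_tsv(annotations: list[AnnotationSet], path) -> None:
    """Per-family counts: total, full-length, pseudogenes (plus partial)."""
    with open(path, "w") as fh:
        fh.write("species\tfamily\ttotal\tfull_length\tpartial\tpseudogenes\n")
        for ann in annotations:
            total, full, part, pseudo = ann.counts
            fh.write(f"{ann.species}\t{ann.family}\t{total}\t{full}\t{part}\t{pseudo}\n")


def write_completeness_tsv(reports: list[CompletenessReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tfound_in_genome\ttotal_by_rnaseq\tmissing\tmin_homology_aa\n")
        for r in reports:
            fh.write(
                f"{r.family}\t{r.transcripts_found_in_annotation}\t{r.transcripts_total}\t"
                f"{r.transcripts_missing}\t{r.min_homology_aa}\n"
            )


def write_pairs_tsv(pairs, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tsupport\n")
        for p in pairs:
            fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.support:.0f}\n")


def write_selection_tsv(results, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pair\tlnL_M7\tlnL_M8\tdelta\tp_value\tkappa\tt\tbeta_p\tbeta_q\tp0\tomega_s\t"
            "positively_selected\tselected_sites\n"
        )
        for r in results:
            sites = ",".join(
                f"{i + 1}:{r.neb_posteriors[i]:.3f}/{r.beb_posteriors[i]:.3f}"
                for i in r.selected_sites
            )
            m7, m8 = r.fit_m7, r.fit_m8
            fh.write(
                f"{r.pair_id}\t{m7.lnL:.4f}\t{m8.lnL:.4f}\t{r.delta:.4f}\t{r.p_value:.4g}\t"
                f"{m8.kappa:.3f}\t{m8.t:.4f}\t{m8.beta_p:.3f}\t{m8.beta_q:.3f}\t"
                f"{m8.p0:.3f}\t{m8.omega_s:.3f}\t{int(r.positively_selected)}\t{sites}\n"
            )


def _attrs(field: str) -> dict[str, str]:
    return dict(kv.split("=", 1) for kv in field.rstrip(";").split(";") if "=" in kv)


def read_truth_gff3(path) -> TruthSet:
    """Read a forge truth GFF3 back (sequences are left empty)."""
    from .genomeforge import TruthRecord

    genes: dict[str, TruthRecord] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sc, _src, ftype, start, end, _score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            a = _attrs(attrs)
            if ftype == "gene":
                genes[a["ID"]] = TruthRecord(
                    gene_id=a["ID"], family=a.get("family", ""), scaffold=sc,
                    strand=strand, exons=[], status=a.get("status", "intact"),
                    protein="", cds="",
                )
            elif ftype == "exon":
                genes[a["Parent"]].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort(reverse=(g.strand == "-"))
    return TruthSet(sorted(genes.values(), key=lambda r: (r.scaffold, r.span)))


def read_models_gff3(path, genome: dict[str, str] | None = None) -> list[GeneModel]:
    """Rebuild gene models from GFF3 (+ genome for CDS/protein)."""
    from .seqs import revcomp, translate

    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            sc, _src, ftype, start, end, score, strand, _phase, attrs = line.rstrip("\n").split("\t")
            a = _attrs(attrs)
            if ftype == "gene":
                models[a["ID"]] = GeneModel(
                    gene_id=a["ID"], locus_id=a["ID"], scaffold_id=sc, strand=strand,
                    exons=[], cds="", protein="",
                    model_score=float(score) if score not in (".", "") else 0.0,
                    frameshift_events=int(a.get("frameshifts", 0)),
                    internal_stop_count=int(a.get("internal_stops", 0)),
                    reference_id=a.get("reference", ""), family=a.get("family", ""),
                    status=a.get("status", "full"),
                )
            elif ftype == "exon":
                gid = a["Parent"].rsplit(".t", 1)[0]
                models[gid].exons.append((int(start) - 1, int(end)))
    out = []
    for m in models.values():
        m.exons.sort(reverse=(m.strand == "-"))
        if genome is not None:
            cds = "".join(genome[m.scaffold_id][s:e] for s, e in sorted(m.exons))
            if m.strand == "-":
                cds = revcomp(cds)
            m.cds = cds
            m.protein = translate(cds).replace("*", "X")
        out.append(m)
    out.sort(key=lambda m: (m.scaffold_id, min(s for s, _ in m.exons)))
    return out


def read_blast_tab(path, scoring=None) -> list:
    """Read the search module's BLAST-tab output back into HSPs."""
    import math

    from .sixframe import HSP, ScoringScheme

    scoring = scoring or ScoringScheme()
    hsps = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            (qid, sid, pident, length, qs, qe, s1, s2, ev, bits, frame) = line.split("\t")
            frame = int(frame)
            strand = "+" if frame > 0 else "-"
            s1, s2 = int(s1), int(s2)
            sstart, send = (s1 - 1, s2) if strand == "+" else (s2 - 1, s1)
            bits_f = float(bits)
            raw = (bits_f * math.log(2.0) + math.log(scoring.K)) / scoring.lam
            hsps.append(
                HSP(
                    query_id=qid, scaffold_id=sid, frame=frame,
                    query_range=(int(qs) - 1, int(qe)), subject_range=(sstart, send),
                    strand=strand, raw_score=raw, bit_score=bits_f, evalue=float(ev),
                    pident=float(pident), aln_length=int(length),
                )
            )
    return hsps


def write_manifest(config_dict: dict, path, version: str = "0.1.0") -> None:
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    manifest = {
        "version": version,
        "config": config_dict,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
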