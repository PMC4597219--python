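"""File-format plumbing: FASTA/FASTQ via Biopython, GFF3 gene models, TSV/YAML.

Only the thin format layer lives here; all science stays in the other
modules.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import DesignRules, GeneModel, TargetSite, Transcript


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    records = []
    for i, r in enumerate(reads):
        rec = SeqRecord(Seq(r), id=f"{prefix}{i + 1}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(r)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gene_models(path: str | Path) -> list[tuple[str, GeneModel]]:
    """Load gene models from a GFF3 file (gene/mRNA/CDS features).

    CDS rows are grouped by their Parent transcript and transcripts by
    their Parent gene; coordinates are converted from GFF3 1-based closed
    to 0-based half-open.
    """
    tr_cds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    tr_meta: dict[str, tuple[str, str, str]] = {}  # tid -> (chrom, strand, gene)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = cols[:9]
            a = _gff_attributes(attrs)
            if ftype == "mRNA":
                tr_meta[a["ID"]] = (chrom, strand, a.get("Parent", a["ID"]))
            elif ftype == "CDS":
                tr_cds[a["Parent"]].append((int(start) - 1, int(end)))
    by_gene: dict[str, list[Transcript]] = defaultdict(list)
    gene_chrom: dict[str, str] = {}
    for tid, intervals in tr_cds.items():
        chrom, strand, gene = tr_meta.get(tid, ("", "+", tid))
        by_gene[gene].append(Transcript(tid, strand, tuple(sorted(intervals))))
        gene_chrom[gene] = chrom
    return [
        (gene_chrom[g], GeneModel(g, tuple(trs))) for g, trs in sorted(by_gene.items())
    ]


def write_gene_models(
    genes: Iterable[tuple[str, GeneModel]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, gene in genes:
            lo = min(s for t in gene.transcripts for s, _ in t.cds)
            hi = max(e for t in gene.transcripts for _, e in t.cds)
            strand = gene.transcripts[0].strand
            fh.write(
                f"{chrom}\tsgarray\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\tID={gene.gene_id}\n"
            )
            for tr in gene.transcripts:
                tlo = min(s for s, _ in tr.cds)
                thi = max(e for _, e in tr.cds)
                fh.write(
                    f"{chrom}\tsgarray\tmRNA\t{tlo + 1}\t{thi}\t.\t{tr.strand}\t.\t"
                    f"ID={tr.transcript_id};Parent={gene.gene_id}\n"
                )
                for s, e in tr.cds:
                    fh.write(
                        f"{chrom}\tsgarray\tCDS\t{s + 1}\t{e}\t.\t{tr.strand}\t0\t"
                        f"ID={tr.transcript_id}.cds;Parent={tr.transcript_id}\n"
                    )


def sites_to_frame(sites: Mapping[str, TargetSite]) -> pd.DataFrame:
    rows = []
    for gene_id, s in sites.items():
        f14, f15, f18 = s.positional_flags
        rows.append(
            dict(
                gene_id=gene_id, chrom=s.chrom, start=s.genome_start,
                strand=s.strand, protospacer=s.protospacer, pam=s.pam,
                gc_2_20=round(s.gc_2_20, 4), seed_unique=s.seed_unique,
                at14=f14, at15=f15, cg18=f18,
                cds_fraction=round(s.cds_fraction, 4),
            )
        )
    return pd.DataFrame(rows)


def write_sites_tsv(sites: Mapping[str, TargetSite], path: str | Path) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_protospacer_fasta(sites: Mapping[str, TargetSite], path: str | Path) -> None:
    write_fasta({g: s.protospacer for g, s in sites.items()}, path)


def write_chip_order_tsv(oligos: Mapping[str, str], path: str | Path) -> None:
    """Chip synthesis order sheet: member id and full oligo sequence."""
    pd.DataFrame(
        [{"member_id": k, "oligo": v, "length": len(v)} for k, v in oligos.items()]
    ).to_csv(path, sep="\t", index=False)


def load_rules(path: str | Path | None) -> DesignRules:
    if path is None:
        return DesignRules()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return DesignRules(**data)


def write_allocations_tsv(allocations, path: str | Path) -> None:
    rows = []
    for a in allocations:
        rows.append(
            dict(
                spacer=a.spacer, status=a.status,
                set=a.address.set_index + 1 if a.address else "",
                plate=a.address.plate + 1 if a.address else "",
                well=a.address.well if a.address else "",
                position_reads=a.position_reads, group_reads=a.group_reads,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
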