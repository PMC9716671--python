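"""File-format helpers: FASTA via Biopython, BED/GFF3 annotation writers.

BED intervals are 0-based half-open; GFF3 is 1-based closed. Both writers
emit the same gene set so either dialect can feed downstream tools.
"""
from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import AnnotatedGenome, Gene


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        for g in genome.genes:
            fh.write(f"{genome.id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_gff(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};category={g.category}"
            fh.write(
                f"{genome.id}\tstrataphy\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_bed(path, genome_id: str | None = None) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if genome_id is not None and fields[0] != genome_id:
                continue
            name = fields[3] if len(fields) > 3 else f"feat{len(genes) + 1}"
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(Gene(name, int(fields[1]), int(fields[2]), strand, "core"))
    return genes
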