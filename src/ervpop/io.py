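"""Readers and writers for the pipeline's on-disk formats.

FASTA goes through Biopython, VCF through pysam; BED is 0-based half-open;
GFF3 output converts the library's 0-based half-open coordinates to 1-based
inclusive. Methylation tracks use a bedMethyl-like TSV (seq, pos, score).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Demography, ErvElement, HaplotypeSet, MethylationTrack

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_hapset",
    "read_hapset",
    "write_bed",
    "read_bed",
    "write_elements_gff3",
    "write_vcf",
    "read_vcf",
    "write_methylation_tsv",
    "read_methylation_tsv",
    "write_demography",
    "read_demography",
]


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_hapset(hapset: HaplotypeSet, fasta_path: str | Path, labels_path: str | Path) -> None:
    """A haplotype set as an aligned FASTA plus a class-label TSV."""
    write_fasta(dict(zip(hapset.names, hapset.seqs)), fasta_path)
    pd.DataFrame(
        {"haplotype": hapset.names, "class_label": [hapset.labels[n] for n in hapset.names]}
    ).to_csv(labels_path, sep="\t", index=False)


def read_hapset(
    fasta_path: str | Path, labels_path: str | Path, seq_name: str = "region"
) -> HaplotypeSet:
    seqs = read_fasta(fasta_path)
    labels_df = pd.read_csv(labels_path, sep="\t")
    labels = dict(zip(labels_df["haplotype"], labels_df["class_label"]))
    names = list(seqs)
    return HaplotypeSet(
        names=names, seqs=[seqs[n] for n in names], labels=labels, seq_name=seq_name
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open). Expects columns seq_name, start, end and
    optionally name/score/strand; extra columns are dropped."""
    cols = [c for c in ["seq_name", "start", "end", "name", "score", "strand"] if c in intervals]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["seq_name", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None)
    df.columns = names[: df.shape[1]]
    return df


def element_to_bed(element: ErvElement, name: str = "erv") -> pd.DataFrame:
    rows = [
        {"seq_name": element.seq_name, "start": element.start, "end": element.end,
         "name": name},
        {"seq_name": element.seq_name, "start": element.ltr5[0], "end": element.ltr5[1],
         "name": f"{name}_ltr5"},
        {"seq_name": element.seq_name, "start": element.ltr3[0], "end": element.ltr3[1],
         "name": f"{name}_ltr3"},
    ]
    return pd.DataFrame(rows)


def write_elements_gff3(
    elements: list[ErvElement], path: str | Path, source: str = "ervpop"
) -> None:
    """Elements with LTRs and ORFs as child features; GFF3 is 1-based
    inclusive, converted here from the library's half-open coordinates."""
    lines = ["##gff-version 3"]
    for i, el in enumerate(elements):
        eid = f"erv{i}"
        attrs = f"ID={eid};ltr_identity={el.ltr_identity:.4f}"
        if el.tsd:
            attrs += f";tsd={el.tsd}"
        lines.append(
            "\t".join(
                [el.seq_name, source, "mobile_genetic_element",
                 str(el.start + 1), str(el.end), ".", "+", ".", attrs]
            )
        )
        for tag, (a, b) in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
            lines.append(
                "\t".join(
                    [el.seq_name, source, "long_terminal_repeat",
                     str(a + 1), str(b), ".", "+", ".",
                     f"ID={eid}_{tag};Parent={eid}"]
                )
            )
        for j, ((a, b), strand, frame) in enumerate(el.orfs):
            lines.append(
                "\t".join(
                    [el.seq_name, source, "open_reading_frame",
                     str(a + 1), str(b), ".", strand, str(frame),
                     f"ID={eid}_orf{j};Parent={eid}"]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_vcf(
    genotypes: np.ndarray,
    path: str | Path,
    positions: np.ndarray | None = None,
    seq_name: str = "chr1",
    sample_names: list[str] | None = None,
    contig_length: int | None = None,
) -> None:
    """Diploid genotype matrix (individuals x sites, alt-allele counts in
    {0,1,2}) as an uncompressed VCF with GT fields and 1-based positions."""
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    if positions is None:
        positions = np.arange(m)
    if sample_names is None:
        sample_names = [f"ind_{i}" for i in range(n)]
    header = pysam.VariantHeader()
    header.add_line(
        f"##contig=<ID={seq_name},length={contig_length or int(positions[-1]) + 2}>"
    )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for name in sample_names:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j in range(m):
            rec = vcf.new_record(
                contig=seq_name,
                start=int(positions[j]),  # pysam converts to 1-based POS
                alleles=("A", "T"),
            )
            for i, name in enumerate(sample_names):
                g = int(genotypes[i, j])
                rec.samples[name]["GT"] = (0, 0) if g == 0 else ((0, 1) if g == 1 else (1, 1))
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Returns (genotype matrix, 0-based positions, sample names)."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        rows, positions = [], []
        for rec in vcf:
            positions.append(rec.start)
            rows.append(
                [sum(a or 0 for a in rec.samples[s]["GT"]) for s in samples]
            )
    return np.array(rows, dtype=np.int8).T, np.array(positions), samples


def write_methylation_tsv(track: MethylationTrack, path: str | Path) -> None:
    pd.DataFrame(
        {"seq_name": track.seq_name, "pos": track.positions, "score": track.scores}
    ).to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> MethylationTrack:
    df = pd.read_csv(path, sep="\t")
    names = df["seq_name"].unique()
    if len(names) != 1:
        raise ValueError("expected a single-sequence methylation track")
    return MethylationTrack(
        seq_name=str(names[0]),
        positions=df["pos"].to_numpy(),
        scores=df["score"].to_numpy(),
    )


def write_demography(demography: Demography, path: str | Path) -> None:
    Path(path).write_text(demography.to_json() + "\n")


def read_demography(path: str | Path) -> Demography:
    return Demography.from_json(Path(path).read_text())
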