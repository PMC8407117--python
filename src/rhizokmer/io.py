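"""File-format helpers shared by the CLI and the pipeline."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotation import GenomeAnnotation, read_gff3


def read_fasta(path: str | Path) -> dict[str, str]:
    """Record id -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_genome_dir(path: str | Path,
                    suffixes: tuple[str, ...] = (".fasta", ".fa", ".fna")
                    ) -> dict[str, dict[str, str]]:
    """Strain id (file stem) -> replicon id -> sequence."""
    genomes = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix.lower() in suffixes:
            genomes[p.stem] = read_fasta(p)
    if not genomes:
        raise FileNotFoundError(f"no FASTA files under {path}")
    return genomes


def read_gff_dir(path: str | Path) -> dict[str, GenomeAnnotation]:
    anns = {}
    for p in sorted(Path(path).iterdir()):
        if p.suffix.lower() in (".gff", ".gff3"):
            anns[p.stem] = read_gff3(p, strain=p.stem)
    if not anns:
        raise FileNotFoundError(f"no GFF3 files under {path}")
    return anns


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column TSV (strain_id, value) -> Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(dtype=float),
                     index=df.iloc[:, 0].astype(str))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False,
              float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def write_matrix_tsv(matrix, path: str | Path, sparse: bool = False) -> None:
    """K-mer count matrix as TSV, optionally as (kmer, strain, count)
    triplets for sparse output."""
    if sparse:
        df = matrix.to_frame().stack().rename("count").reset_index()
        df.columns = ["kmer", "strain", "count"]
        df = df[df["count"] > 0]
        write_tsv(df, path)
    else:
        write_tsv(matrix.to_frame().reset_index(), path)
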