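"""Genome annotations: replicons and gene features, with GFF3 I/O.

Coordinates are 1-based inclusive throughout (GFF3 convention); any
half-open exchange format (e.g. BED) is converted at the I/O boundary.
Replicons carry a role tag -- chromosome, pSymA-like (symbiosis
megaplasmid), pSymB-like (chromid) or other -- used when summarizing
where k-mer hits land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils

REPLICON_ROLES = ("chromosome", "pSymA-like", "pSymB-like", "other")


def infer_replicon_role(name: str) -> str:
    low = name.lower()
    if "psyma" in low:
        return "pSymA-like"
    if "psymb" in low:
        return "pSymB-like"
    if "chromosome" in low or "chrom" in low:
        return "chromosome"
    return "other"


@dataclass(frozen=True)
class Replicon:
    id: str
    length: int
    role: str = "other"


@dataclass(frozen=True)
class Gene:
    replicon: str
    start: int          # 1-based inclusive
    end: int            # 1-based inclusive
    strand: str         # '+' or '-'
    locus_tag: str
    cog_id: str | None = None
    ortholog_group: str | None = None
    product: str | None = None

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"bad gene interval {self.start}..{self.end} ({self.locus_tag})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} ({self.locus_tag})")


@dataclass
class GenomeAnnotation:
    """Annotation of one strain: replicons plus gene features."""

    strain: str
    replicons: dict[str, Replicon]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self):
        tags = [g.locus_tag for g in self.genes]
        if len(tags) != len(set(tags)):
            raise ValueError(f"duplicate locus_tag in strain {self.strain}")
        for g in self.genes:
            rep = self.replicons.get(g.replicon)
            if rep is None:
                raise ValueError(
                    f"gene {g.locus_tag} on unknown replicon {g.replicon}")
            if g.end > rep.length:
                raise ValueError(
                    f"gene {g.locus_tag} extends past replicon end")

    def genes_on(self, replicon: str) -> list[Gene]:
        return [g for g in self.genes if g.replicon == replicon]

    def ortholog_groups(self) -> set[str]:
        return {g.ortholog_group for g in self.genes if g.ortholog_group}


def _attr(parts: list[str]) -> str:
    return ";".join(parts)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Emit a minimal GFF3: region features per replicon, gene features
    with ID, locus_tag and optional cog_id / ortholog_group / product."""
    lines = ["##gff-version 3"]
    for rep in annotation.replicons.values():
        lines.append(f"##sequence-region {rep.id} 1 {rep.length}")
    for rep in annotation.replicons.values():
        lines.append("\t".join([
            rep.id, "rhizokmer", "region", "1", str(rep.length), ".", "+",
            ".", _attr([f"ID={rep.id}", f"replicon_role={rep.role}"])]))
    for g in annotation.genes:
        attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
        if g.cog_id:
            attrs.append(f"cog_id={g.cog_id}")
        if g.ortholog_group:
            attrs.append(f"ortholog_group={g.ortholog_group}")
        if g.product:
            attrs.append(f"product={g.product}")
        lines.append("\t".join([
            g.replicon, "rhizokmer", "gene", str(g.start), str(g.end), ".",
            g.strand, ".", _attr(attrs)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, strain: str,
              replicon_lengths: dict[str, int] | None = None
              ) -> GenomeAnnotation:
    """Parse a GFF3 file into a GenomeAnnotation.

    Replicon lengths and roles come from ``region`` features (or
    ``##sequence-region`` directives via ``replicon_lengths``); roles
    fall back to name-based inference when no ``replicon_role``
    attribute is present.
    """
    path = Path(path)
    db = gffutils.create_db(str(path), dbfn=":memory:",
                            force=True, keep_order=True,
                            merge_strategy="create_unique")
    replicons: dict[str, Replicon] = {}
    for feat in db.features_of_type("region"):
        role = feat.attributes.get("replicon_role",
                                   [infer_replicon_role(feat.seqid)])[0]
        replicons[feat.seqid] = Replicon(id=feat.seqid, length=feat.end,
                                         role=role)
    # fall back to ##sequence-region directives for length
    for line in path.read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, seqid, start, end = line.split()[:4]
            if seqid not in replicons:
                replicons[seqid] = Replicon(
                    id=seqid, length=int(end),
                    role=infer_replicon_role(seqid))
    if replicon_lengths:
        for seqid, ln in replicon_lengths.items():
            if seqid not in replicons:
                replicons[seqid] = Replicon(
                    id=seqid, length=ln, role=infer_replicon_role(seqid))
    genes = []
    for feat in db.features_of_type(("gene", "CDS")):
        a = feat.attributes
        tag = a.get("locus_tag", a.get("ID", [feat.id]))[0]
        genes.append(Gene(
            replicon=feat.seqid, start=feat.start, end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            locus_tag=tag,
            cog_id=a.get("cog_id", [None])[0],
            ortholog_group=a.get("ortholog_group", [None])[0],
            product=a.get("product", [None])[0]))
    # a gene may appear as both gene and CDS records: keep first per tag
    seen: set[str] = set()
    uniq = []
    for g in genes:
        if g.locus_tag in seen:
            continue
        seen.add(g.locus_tag)
        uniq.append(g)
    return GenomeAnnotation(strain=strain, replicons=replicons, genes=uniq)
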