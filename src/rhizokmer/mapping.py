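"""Locate significant k-mers on annotated genomes and classify hits.

Each occurrence of a k-mer (searched on both strands) is classified as
a CDS hit when it overlaps a gene interval by at least one base, as a
regulatory hit when it instead overlaps the strand-aware 600-nt window
upstream of a CDS start, and as intergenic otherwise.  CDS takes
precedence over regulatory at the same occurrence.  One k-mer may tag
multiple genes.  Hits are then summarized per strain by COG category,
ortholog group and replicon role, and clustered into carrier-exclusive
accessory regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation
from .kmers import canonicalize, kmer_to_code, window_codes

DEFAULT_UPSTREAM = 600
DEFAULT_REGION_GAP = 5_000

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class KmerOccurrence:
    kmer: str          # canonical form
    strain: str
    replicon: str
    position: int      # 1-based leftmost base on the forward strand
    strand: str        # strand on which the canonical form matches


@dataclass(frozen=True)
class KmerHit:
    kmer: str
    strain: str
    replicon: str
    position: int
    strand: str
    context: str                    # 'CDS' | 'regulatory' | 'intergenic'
    locus_tag: str | None = None
    cog_id: str | None = None
    ortholog_group: str | None = None
    distance_to_start: int | None = None   # regulatory only, in [1, 600]


def locate_kmers(kmers: Iterable[str],
                 genomes: Mapping[str, Mapping[str, str]]
                 ) -> list[KmerOccurrence]:
    """Exact search of each k-mer and its reverse complement over every
    replicon of every strain; all (overlapping) occurrences reported.

    The scan slides once over each replicon comparing 2-bit window
    codes against the sorted query codes, so runtime is linear in
    genome size rather than in (genomes x queries).
    """
    by_len: dict[int, list[str]] = {}
    for km in {canonicalize(k) for k in kmers}:
        by_len.setdefault(len(km), []).append(km)
    occ: list[KmerOccurrence] = []
    for k, group in sorted(by_len.items()):
        group = sorted(group)
        fwd_q = np.array([kmer_to_code(km) for km in group])
        rc_q = np.array([kmer_to_code(revcomp(km)) for km in group])
        names = np.array(group, dtype=object)
        f_order = np.argsort(fwd_q)
        r_order = np.argsort(rc_q)
        fq, fn = fwd_q[f_order], names[f_order]
        rq, rn = rc_q[r_order], names[r_order]
        for strain, reps in genomes.items():
            for rep_id, seq in reps.items():
                fwd, _, clean = window_codes(seq.upper(), k,
                                             record_id=f"{strain}/{rep_id}")
                for codes, qnames, strand in ((fq, fn, "+"), (rq, rn, "-")):
                    idx = np.searchsorted(codes, fwd)
                    idx[idx == codes.size] = 0
                    hit = clean & (codes[idx] == fwd)
                    for pos in np.nonzero(hit)[0]:
                        km = qnames[idx[pos]]
                        if strand == "-" and km == revcomp(km):
                            continue  # palindrome: already found on '+'
                        occ.append(KmerOccurrence(km, strain, rep_id,
                                                  int(pos) + 1, strand))
    occ.sort(key=lambda o: (o.strain, o.replicon, o.position, o.kmer,
                            o.strand))
    return occ


def _upstream_window(gene: Gene, upstream: int,
                     replicon_length: int) -> tuple[int, int] | None:
    """Strand-aware upstream window, truncated at the replicon ends."""
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start - 1
    else:
        lo, hi = gene.end + 1, gene.end + upstream
    lo = max(1, lo)
    hi = min(replicon_length, hi)
    if lo > hi:
        return None
    return lo, hi


def classify_hit(occ: KmerOccurrence, annotation: GenomeAnnotation,
                 upstream: int = DEFAULT_UPSTREAM,
                 k: int | None = None) -> list[KmerHit]:
    """Classify one occurrence against a strain's annotation.

    Returns one CDS row per overlapped gene; otherwise one regulatory
    row per gene whose upstream window overlaps the match (with the gap
    from the match's nearest base to the CDS start); otherwise a single
    intergenic row.
    """
    k = k or len(occ.kmer)
    m_lo, m_hi = occ.position, occ.position + k - 1
    rep = annotation.replicons.get(occ.replicon)
    if rep is None:
        raise KeyError(f"occurrence on unknown replicon {occ.replicon!r}")
    genes = annotation.genes_on(occ.replicon)
    rows: list[KmerHit] = []
    for g in genes:
        if m_lo <= g.end and m_hi >= g.start:
            rows.append(KmerHit(occ.kmer, occ.strain, occ.replicon,
                                occ.position, occ.strand, "CDS",
                                locus_tag=g.locus_tag, cog_id=g.cog_id,
                                ortholog_group=g.ortholog_group))
    if rows:
        return rows
    for g in genes:
        win = _upstream_window(g, upstream, rep.length)
        if win is None:
            continue
        lo, hi = win
        if m_lo <= hi and m_hi >= lo:
            if g.strand == "+":
                dist = g.start - m_hi
            else:
                dist = m_lo - g.end
            rows.append(KmerHit(occ.kmer, occ.strain, occ.replicon,
                                occ.position, occ.strand, "regulatory",
                                locus_tag=g.locus_tag, cog_id=g.cog_id,
                                ortholog_group=g.ortholog_group,
                                distance_to_start=int(dist)))
    if rows:
        return rows
    return [KmerHit(occ.kmer, occ.strain, occ.replicon, occ.position,
                    occ.strand, "intergenic")]


def classify_hits(occurrences: Iterable[KmerOccurrence],
                  annotations: Mapping[str, GenomeAnnotation],
                  upstream: int = DEFAULT_UPSTREAM) -> pd.DataFrame:
    """Classify all occurrences; returns a tidy hit table."""
    rows = []
    for occ in occurrences:
        for hit in classify_hit(occ, annotations[occ.strain], upstream):
            rows.append(hit.__dict__)
    cols = ["kmer", "strain", "replicon", "position", "strand", "context",
            "locus_tag", "cog_id", "ortholog_group", "distance_to_start"]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class HitSummary:
    cds_by_cog: pd.DataFrame           # strain x COG distinct-gene counts
    cds_by_ortholog: pd.DataFrame      # strain x ortholog-group counts
    regulatory_by_gene: pd.DataFrame   # rows: strain, locus_tag, n_hits
    replicon_fractions: pd.DataFrame   # strain x role, all hits
    ortholog_replicon_fractions: pd.DataFrame  # ortholog-gene hits only
    unannotated_cds: pd.Series         # strain -> distinct genes w/o COG
    core_flags: pd.Series | None = None  # locus-free: ortholog -> core?


def summarize_hits(hits: pd.DataFrame,
                   annotations: Mapping[str, GenomeAnnotation],
                   gene_presence: pd.DataFrame | None = None) -> HitSummary:
    """Summaries of a hit table (counts of *distinct* tagged genes).

    ``gene_presence`` is an optional ortholog-group x strain binary
    table; groups present in every strain are flagged core.
    """
    if hits.empty:
        raise ValueError("hit table is empty")
    roles = {}
    for strain, ann in annotations.items():
        for rep in ann.replicons.values():
            roles[(strain, rep.id)] = rep.role
    h = hits.copy()
    h["role"] = [roles.get((s, r), "other")
                 for s, r in zip(h["strain"], h["replicon"])]

    cds = h[h["context"] == "CDS"]
    genes = cds.drop_duplicates(["strain", "locus_tag"])
    with_cog = genes[genes["cog_id"].notna()]
    cds_by_cog = (with_cog.groupby(["strain", "cog_id"]).size()
                  .unstack(fill_value=0))
    with_og = genes[genes["ortholog_group"].notna()]
    cds_by_ortholog = (with_og.groupby(["strain", "ortholog_group"]).size()
                       .unstack(fill_value=0))
    unannotated = (genes[genes["cog_id"].isna()]
                   .groupby("strain").size())

    reg = h[h["context"] == "regulatory"]
    regulatory_by_gene = (reg.groupby(["strain", "locus_tag"]).size()
                          .rename("n_hits").reset_index())

    def _fractions(sub: pd.DataFrame) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame()
        counts = sub.groupby(["strain", "role"]).size().unstack(fill_value=0)
        return counts.div(counts.sum(axis=1), axis=0)

    replicon_fractions = _fractions(h)
    ortholog_replicon_fractions = _fractions(
        h[(h["context"].isin(["CDS", "regulatory"])) &
          h["ortholog_group"].notna()])

    core_flags = None
    if gene_presence is not None:
        n_strains = gene_presence.shape[1]
        core_flags = (gene_presence.astype(bool).sum(axis=1) ==
                      n_strains).rename("core")
    return HitSummary(
        cds_by_cog=cds_by_cog,
        cds_by_ortholog=cds_by_ortholog,
        regulatory_by_gene=regulatory_by_gene,
        replicon_fractions=replicon_fractions,
        ortholog_replicon_fractions=ortholog_replicon_fractions,
        unannotated_cds=unannotated,
        core_flags=core_flags)


def carrier_exclusive_region(hits: pd.DataFrame,
                             annotations: Mapping[str, GenomeAnnotation],
                             carrier_set: set[str] | frozenset[str],
                             gap: int = DEFAULT_REGION_GAP) -> list[dict]:
    """Cluster hits into regions and keep those whose ortholog-group
    content occurs in exactly the carrier strains.

    Hit positions on each (strain, replicon) are clustered into maximal
    runs with inter-hit gap <= ``gap``.  A region qualifies when every
    ortholog group tagged inside it is annotated in all carriers and in
    no other strain.  A carrier set equal to the whole panel can have no
    exclusive region by definition.
    """
    carrier_set = frozenset(carrier_set)
    if carrier_set == frozenset(annotations):
        return []
    # which strains annotate each ortholog group
    og_strains: dict[str, set[str]] = {}
    for strain, ann in annotations.items():
        for og in ann.ortholog_groups():
            og_strains.setdefault(og, set()).add(strain)
    regions = []
    for (strain, replicon), sub in hits.groupby(["strain", "replicon"]):
        pos = sorted(sub["position"].unique())
        clusters: list[list[int]] = [[pos[0]]]
        for p in pos[1:]:
            if p - clusters[-1][-1] <= gap:
                clusters[-1].append(p)
            else:
                clusters.append([p])
        for cl in clusters:
            lo, hi = cl[0], cl[-1]
            inside = sub[(sub["position"] >= lo) & (sub["position"] <= hi)]
            ogs = sorted(set(inside["ortholog_group"].dropna()))
            if not ogs:
                continue
            if all(og_strains.get(og, set()) == carrier_set for og in ogs):
                regions.append({
                    "strain": strain, "replicon": replicon,
                    "start": int(lo), "end": int(hi),
                    "n_hits": int(len(inside)),
                    "ortholog_groups": ogs,
                    "locus_tags": sorted(set(inside["locus_tag"].dropna())),
                })
    regions.sort(key=lambda r: (r["strain"], r["replicon"], r["start"]))
    return regions


def hits_to_bed(hits: pd.DataFrame, path: str | Path) -> None:
    """Write hit positions as BED (0-based half-open at the boundary)."""
    with open(path, "w") as fh:
        for _, r in hits.drop_duplicates(
                ["strain", "replicon", "position", "kmer"]).iterrows():
            start0 = int(r["position"]) - 1
            end0 = start0 + len(r["kmer"])
            fh.write(f"{r['replicon']}\t{start0}\t{end0}\t"
                     f"{r['strain']}|{r['kmer']}\t0\t{r['strand']}\n")
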