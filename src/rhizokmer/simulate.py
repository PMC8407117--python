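"""Synthetic study generator: genomes, annotations, phenotypes, counts.

Emulates the structure of a rhizobium competition study: a panel of
tester strains (13 by default) with three replicons each (a chromosome
and two megaplasmid-like replicons), a shared core genome with SNPs,
accessory blocks private to strain subsets -- including one causal
block on the pSymA-like replicon carried by exactly the
high-competitiveness strains -- a continuous nodule-occupancy phenotype
in [0, 1] driven by the causal block plus Gaussian noise, and
per-plant nodule colour counts (six plants per competition).

Replicons are emitted as linear sequences (assemblies are consumed as
linear FASTA records) and background sequence is i.i.d. uniform over
A/C/G/T, which maximizes the number of distinct 13-mers.  The
generator guarantees that multi-strain k-mer presence/absence patterns
arise only from planted structure: accessory blocks and strain-private
tails are drawn pairwise k-mer-disjoint (colliding windows are
repaired), and core substitutions are strain singletons spaced at
least k apart, so point variation never creates a shared
absence pattern.  Chance collisions between a block and the shared
core remain possible and are resolved exactly when the causal k-mer
truth set is computed (present in every carrier, absent from every
non-carrier).  The default causal block is a 2-kb stand-in for the
~26-kb accessory region of the real genomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .annotation import Gene, GenomeAnnotation, Replicon, write_gff3
from .kmers import DEFAULT_K, sequence_kmer_codes, code_to_kmer

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)

# COG ids cycled over simulated genes (real categories; the causal block
# reuses the regulator families typical of accessory symbiosis regions)
_CORE_COGS = ("COG0583", "COG1282", "COG0745", "COG2188", "COG1028",
              "COG0515")
_CAUSAL_COGS = ("COG1529", "COG2188")
_MIN_BLOCK_LEN = 800  # room for one gene with a 600-nt clear upstream


class SizingError(ValueError):
    """A replicon cannot accommodate its accessory blocks."""


@dataclass(frozen=True)
class AccessoryBlock:
    block_id: str
    length: int
    replicon_index: int
    carriers: tuple[str, ...]


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the analysed study design: 13 strains, 3 replicons,
    a causal accessory block on the pSymA-like replicon carried by the
    4 top competitors, occupancy 0.25 baseline + 0.40 causal effect
    with N(0, 0.05) noise, 6 plants per competition.
    """

    n_strains: int = 13
    n_replicons: int = 3
    replicon_lengths: tuple[int, ...] = (60_000, 40_000, 30_000)
    replicon_names: tuple[str, ...] = ("chromosome", "pSymA", "pSymB")
    core_fraction: float = 0.9
    snp_rate: float = 0.001   # substitutions per core bp per strain
    accessory_blocks: tuple[AccessoryBlock, ...] | None = None
    causal_block_id: str | None = "blkSym"
    base_occupancy: float = 0.25
    beta: float = 0.40
    noise_sd: float = 0.05
    p_mix: float = 0.15
    plants_per_competition: int = 6
    nodules_per_plant_mean: float = 20.0
    competition_id: str = "vs_REF"
    k: int = DEFAULT_K
    seed: int = 0

    def __post_init__(self):
        if self.accessory_blocks is None:
            if self.causal_block_id is None:
                self.accessory_blocks = ()
            else:
                ids = self.strain_ids
                self.accessory_blocks = (
                    AccessoryBlock("blkSym", 2_000, 1, tuple(ids[:4])),
                    AccessoryBlock("blkAcc1", 1_200, 0, tuple(ids[4:8])),
                    AccessoryBlock("blkAcc2", 800, 2,
                                   (ids[2], ids[8], ids[9])),
                )
        self.validate()

    @property
    def strain_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]

    def validate(self) -> None:
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must lie in [0, 1]")
        if len(self.replicon_lengths) != self.n_replicons:
            raise ValueError("one length per replicon required")
        if any(ln < self.k for ln in self.replicon_lengths):
            raise ValueError(f"replicon lengths must be >= k={self.k}")
        ids = set(self.strain_ids)
        block_ids = set()
        per_replicon: dict[int, int] = {}
        for b in self.accessory_blocks:
            if b.block_id in block_ids:
                raise ValueError(f"duplicate block id {b.block_id}")
            block_ids.add(b.block_id)
            carriers = set(b.carriers)
            if not carriers or carriers >= ids or not carriers <= ids:
                raise ValueError(
                    f"block {b.block_id}: carriers must be a nonempty proper "
                    f"subset of the strain panel")
            if b.length < _MIN_BLOCK_LEN:
                raise ValueError(
                    f"block {b.block_id}: length must be >= {_MIN_BLOCK_LEN} "
                    f"to hold an annotated gene with clear upstream")
            if not 0 <= b.replicon_index < self.n_replicons:
                raise ValueError(f"block {b.block_id}: bad replicon index")
            per_replicon[b.replicon_index] = (
                per_replicon.get(b.replicon_index, 0) + b.length)
        if self.causal_block_id is not None and \
                self.causal_block_id not in block_ids:
            raise ValueError(
                f"causal_block_id {self.causal_block_id!r} names no block")
        for r, tot in per_replicon.items():
            core_len = int(round(self.core_fraction *
                                 self.replicon_lengths[r]))
            if core_len < tot:
                raise SizingError(
                    f"replicon {r} core ({core_len} bp) shorter than the "
                    f"sum of its accessory blocks ({tot} bp)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "accessory_blocks" in raw and raw["accessory_blocks"] is not None:
            raw["accessory_blocks"] = tuple(
                AccessoryBlock(b["block_id"], int(b["length"]),
                               int(b["replicon_index"]),
                               tuple(b["carriers"]))
                for b in raw["accessory_blocks"])
        for key in ("replicon_lengths", "replicon_names"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth of one simulated panel."""

    carrier_map: dict[str, frozenset[str]]
    causal_kmers: frozenset[str]
    block_locations: dict[str, dict[str, tuple[str, int, int]]]
    planted_gene_coords: dict[str, list[Gene]]
    true_phenotype: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "carrier_map": {k: sorted(v) for k, v in self.carrier_map.items()},
            "causal_kmers": sorted(self.causal_kmers),
            "block_locations": {
                b: {s: list(loc) for s, loc in sorted(d.items())}
                for b, d in self.block_locations.items()},
            "planted_genes": {
                s: [g.__dict__ for g in genes]
                for s, genes in sorted(self.planted_gene_coords.items())},
            "true_phenotype": (None if self.true_phenotype is None else
                               {k: float(v)
                                for k, v in self.true_phenotype.items()}),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _decode(codes: np.ndarray) -> str:
    return _LUT[codes].tobytes().decode("ascii")


def _block_gene_layout(length: int) -> list[tuple[int, int, str]]:
    """Gene intervals (1-based, within-block) for a block of ``length``.

    The first gene starts at offset 701 so its 600-nt upstream window is
    clear of other features inside the block.
    """
    genes = [(701, min(1_500, length - 50), "+")]
    if length - 1_600 >= 300:
        genes.append((1_601, length - 100, "+"))
    return genes


def simulate_genomes(cfg: SimConfig):
    """Generate the strain panel.

    Returns ``(genomes, annotations, truth)`` where ``genomes`` maps
    strain id -> replicon record id -> sequence, ``annotations`` maps
    strain id -> GenomeAnnotation, and ``truth`` records carrier sets,
    causal k-mers and planted gene coordinates.  Regeneration with the
    same config and seed is byte-identical.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    strains = cfg.strain_ids
    k = cfg.k

    # 1. shared core backbones
    backbones: list[np.ndarray] = []
    core_lens = []
    for r in range(cfg.n_replicons):
        L = cfg.replicon_lengths[r]
        core_len = int(round(cfg.core_fraction * L))
        core_lens.append(core_len)
        backbones.append(rng.integers(0, 4, core_len, dtype=np.int8))

    # 2. fixed insertion loci per replicon
    blocks_by_rep: dict[int, list[AccessoryBlock]] = {}
    for b in cfg.accessory_blocks:
        blocks_by_rep.setdefault(b.replicon_index, []).append(b)
    loci: dict[str, int] = {}  # block id -> 0-based backbone offset
    for r, bs in blocks_by_rep.items():
        for i, b in enumerate(sorted(bs, key=lambda b: b.block_id)):
            loci[b.block_id] = core_lens[r] * (i + 1) // (len(bs) + 1)

    # 3. global k-mer bookkeeping: every piece of non-core content
    # (blocks, substituted windows, private tails) is kept k-mer
    # disjoint from everything drawn before it, so presence/absence
    # patterns arise only from planted structure
    taken: set[int] = set()
    for bb in backbones:
        taken.update(sequence_kmer_codes(_decode(bb), k).tolist())

    def _draw_disjoint(length: int, label: str) -> np.ndarray:
        seq = rng.integers(0, 4, length, dtype=np.int8)
        for _ in range(60):
            codes = sequence_kmer_codes(_decode(seq), k)
            bad = [i for i, c in enumerate(codes.tolist()) if c in taken]
            if not bad:
                taken.update(codes.tolist())
                return seq
            for i in bad:
                j = i + int(rng.integers(0, k))
                seq[j] = (seq[j] + int(rng.integers(1, 4))) % 4
        raise RuntimeError(f"could not draw disjoint sequence for {label}")

    # accessory blocks, plus their carrier-shared junction windows
    block_seqs: dict[str, np.ndarray] = {}
    for b in cfg.accessory_blocks:
        block_seqs[b.block_id] = _draw_disjoint(b.length, b.block_id)
        cut = loci[b.block_id]
        bb = backbones[b.replicon_index]
        jseq = np.concatenate([bb[max(0, cut - (k - 1)):cut],
                               block_seqs[b.block_id],
                               bb[cut:cut + (k - 1)]])
        taken.update(sequence_kmer_codes(_decode(jseq), k).tolist())

    # 4. strain-singleton substitutions on the core: each polymorphic
    # site belongs to exactly one strain, sites sit >= k apart and away
    # from insertion loci, and the substituted windows are collision
    # checked, so point variation never creates a multi-strain absence
    # pattern (the min/max filter then removes all of it)
    snps: list[list[np.ndarray]] = []
    for r in range(cfg.n_replicons):
        core_len = core_lens[r]
        n_sites = int(round(cfg.snp_rate * core_len * cfg.n_strains))
        forbidden = [loci[b.block_id] for b in blocks_by_rep.get(r, [])]
        cand = np.sort(rng.integers(0, max(core_len - k, 1),
                                    size=4 * n_sites + 16))
        sites: list[int] = []
        last = -k
        for pos in cand:
            if len(sites) >= n_sites:
                break
            pos = int(pos)
            if pos - last >= k and all(abs(pos - c) >= 2 * k
                                       for c in forbidden):
                sites.append(pos)
                last = pos
        owners = rng.integers(0, cfg.n_strains, size=len(sites))
        bb = backbones[r]
        row = [bb.copy() for _ in strains]
        for i, pos in enumerate(sites):
            shift_order = 1 + rng.permutation(3)
            lo = max(0, pos - (k - 1))
            for shift in shift_order:
                ctx = bb[lo:pos + k].copy()
                ctx[pos - lo] = (ctx[pos - lo] + shift) % 4
                codes = sequence_kmer_codes(_decode(ctx), k)
                if not any(c in taken for c in codes.tolist()):
                    taken.update(codes.tolist())
                    row[owners[i]][pos] = ctx[pos - lo]
                    break
            # all three substitutions collide (rare): site skipped
        snps.append(row)

    # 5. strain-private tails
    privates: list[list[np.ndarray]] = []  # [replicon][strain]
    for r in range(cfg.n_replicons):
        tail_len = cfg.replicon_lengths[r] - core_lens[r]
        privates.append([_draw_disjoint(tail_len, f"tail r{r} {s}")
                         if tail_len >= k else
                         rng.integers(0, 4, tail_len, dtype=np.int8)
                         for s in strains])

    # 5. core gene layout on backbone coordinates (skip genes that a
    # block insertion point would split)
    core_genes: dict[int, list[tuple[int, int, str, int]]] = {}
    for r in range(cfg.n_replicons):
        lst = []
        gi = 0
        start = 1_000
        cuts = [loci[b.block_id] for b in blocks_by_rep.get(r, [])]
        while start + 900 < core_lens[r] - 100:
            end = start + 899
            if not any(start <= cut <= end for cut in cuts):
                strand = "+" if gi % 2 == 0 else "-"
                lst.append((start, end, strand, gi))
            gi += 1
            start += 5_000
        core_genes[r] = lst

    # 6. assemble per-strain replicons and annotations
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, GenomeAnnotation] = {}
    block_locations: dict[str, dict[str, tuple[str, int, int]]] = {
        b.block_id: {} for b in cfg.accessory_blocks}
    planted: dict[str, list[Gene]] = {b.block_id: [] for b in
                                      cfg.accessory_blocks}
    for si, strain in enumerate(strains):
        reps: dict[str, str] = {}
        replicons: dict[str, Replicon] = {}
        genes: list[Gene] = []
        for r in range(cfg.n_replicons):
            rep_id = f"{strain}_{cfg.replicon_names[r]}"
            bs = sorted(blocks_by_rep.get(r, []),
                        key=lambda b: loci[b.block_id])
            parts: list[np.ndarray] = []
            pos = 0          # consumed backbone prefix (0-based)
            shift = 0        # inserted length so far
            cut_shift: list[tuple[int, int]] = []  # (cut, total shift after)
            for b in bs:
                cut = loci[b.block_id]
                parts.append(snps[r][si][pos:cut])
                if strain in b.carriers:
                    parts.append(block_seqs[b.block_id])
                    start1 = cut + shift + 1        # 1-based block start
                    end1 = cut + shift + b.length
                    block_locations[b.block_id][strain] = (rep_id, start1,
                                                           end1)
                    for gj, (gs, ge, gstrand) in enumerate(
                            _block_gene_layout(b.length)):
                        cogs = (_CAUSAL_COGS if b.block_id ==
                                cfg.causal_block_id else _CORE_COGS)
                        gene = Gene(
                            replicon=rep_id,
                            start=start1 + gs - 1, end=start1 + ge - 1,
                            strand=gstrand,
                            locus_tag=f"{strain}_{b.block_id}_g{gj}",
                            cog_id=cogs[gj % len(cogs)],
                            ortholog_group=f"OG_{b.block_id}_g{gj}",
                            product=f"accessory protein {b.block_id} {gj}")
                        genes.append(gene)
                        planted[b.block_id].append(gene)
                    shift += b.length
                pos = cut
                cut_shift.append((cut, shift))
            parts.append(snps[r][si][pos:])
            parts.append(privates[r][si])
            seq = _decode(np.concatenate(parts))
            reps[rep_id] = seq
            replicons[rep_id] = Replicon(
                id=rep_id, length=len(seq),
                role=("chromosome", "pSymA-like", "pSymB-like")[r]
                if r < 3 else "other")
            for (gs, ge, gstrand, gi) in core_genes[r]:
                off = 0
                for cut, sh in cut_shift:
                    if cut <= gs:
                        off = sh
                genes.append(Gene(
                    replicon=rep_id, start=gs + off + 1, end=ge + off + 1,
                    strand=gstrand,
                    locus_tag=f"{strain}_core_r{r}_g{gi:03d}",
                    cog_id=_CORE_COGS[gi % len(_CORE_COGS)],
                    ortholog_group=f"OGcore_r{r}_g{gi:03d}",
                    product=f"core protein r{r} {gi}"))
        genomes[strain] = reps
        annotations[strain] = GenomeAnnotation(
            strain=strain, replicons=replicons, genes=genes)

    # 7. ground-truth causal k-mers: canonical k-mers of windows
    # overlapping the causal block, present in every carrier and in no
    # non-carrier (covers block-internal and junction-spanning windows)
    causal_block = next((b for b in cfg.accessory_blocks
                         if b.block_id == cfg.causal_block_id), None)
    if causal_block is None:
        return genomes, annotations, SimTruth(
            carrier_map={b.block_id: frozenset(b.carriers)
                         for b in cfg.accessory_blocks},
            causal_kmers=frozenset(),
            block_locations=block_locations,
            planted_gene_coords=planted)
    carriers = set(causal_block.carriers)
    carrier_sets = []
    for strain in sorted(carriers):
        rep_id, start1, end1 = block_locations[cfg.causal_block_id][strain]
        seq = genomes[strain][rep_id]
        lo = max(0, start1 - 1 - (k - 1))
        hi = min(len(seq), end1 + (k - 1))
        carrier_sets.append(set(
            sequence_kmer_codes(seq[lo:hi], k).tolist()))
    shared = set.intersection(*carrier_sets)
    outside = set()
    for strain in strains:
        if strain in carriers:
            continue
        for seq in genomes[strain].values():
            outside.update(sequence_kmer_codes(seq, k).tolist())
    causal_codes = shared - outside
    causal_kmers = frozenset(code_to_kmer(c, k) for c in causal_codes)

    truth = SimTruth(
        carrier_map={b.block_id: frozenset(b.carriers)
                     for b in cfg.accessory_blocks},
        causal_kmers=causal_kmers,
        block_locations=block_locations,
        planted_gene_coords=planted)
    return genomes, annotations, truth


def simulate_phenotype(truth: SimTruth, cfg: SimConfig) -> pd.Series:
    """Occupancy phenotype: base + beta * carrier + N(0, noise_sd),
    clipped to [0, 1]; stored on the truth object."""
    carriers = (truth.carrier_map.get(cfg.causal_block_id, frozenset())
                if cfg.causal_block_id is not None else frozenset())
    rng = np.random.default_rng([cfg.seed, 101])
    strains = cfg.strain_ids
    eps = rng.normal(0.0, cfg.noise_sd, len(strains)) if cfg.noise_sd > 0 \
        else np.zeros(len(strains))
    vals = np.clip([cfg.base_occupancy + cfg.beta * (s in carriers) + e
                    for s, e in zip(strains, eps)], 0.0, 1.0)
    pheno = pd.Series(vals, index=strains, name=cfg.competition_id)
    truth.true_phenotype = pheno
    return pheno


def simulate_nodule_counts(phenotype: pd.Series, cfg: SimConfig
                           ) -> pd.DataFrame:
    """Per-plant nodule colour counts.

    Total nodules per plant ~ Poisson(nodules_per_plant_mean)
    conditioned on >= 1; colours ~ Multinomial(total; p_green =
    phi * (1 - p_mix), p_red = (1 - phi) * (1 - p_mix), p_mixed = p_mix)
    where phi is the strain's occupancy phenotype.
    """
    if ((phenotype < 0) | (phenotype > 1)).any():
        raise ValueError("phenotype must lie in [0, 1]")
    rng = np.random.default_rng([cfg.seed, 202])
    rows = []
    for strain in phenotype.index:
        phi = float(phenotype[strain])
        probs = [phi * (1 - cfg.p_mix), (1 - phi) * (1 - cfg.p_mix),
                 cfg.p_mix]
        for j in range(cfg.plants_per_competition):
            total = 0
            while total < 1:
                total = int(rng.poisson(cfg.nodules_per_plant_mean))
            g, r, m = rng.multinomial(total, probs)
            rows.append((cfg.competition_id, strain, f"plant{j + 1}",
                         int(g), int(r), int(m)))
    return pd.DataFrame(rows, columns=["competition_id", "strain_id",
                                       "plant_id", "n_green", "n_red",
                                       "n_mixed"])


def simulate_study(cfg: SimConfig):
    """Full synthetic study: genomes + phenotype + nodule counts."""
    genomes, annotations, truth = simulate_genomes(cfg)
    pheno = simulate_phenotype(truth, cfg)
    counts = simulate_nodule_counts(pheno, cfg)
    return genomes, annotations, truth, pheno, counts


def write_simulation(outdir: str | Path, genomes, annotations, truth,
                     counts: pd.DataFrame | None = None) -> None:
    """Write FASTA (80-column wrap), GFF3, the truth JSON and, when
    given, the nodule-count TSV."""
    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "gff").mkdir(parents=True, exist_ok=True)
    for strain, reps in genomes.items():
        with open(out / "genomes" / f"{strain}.fasta", "w") as fh:
            for rep_id, seq in reps.items():
                fh.write(f">{rep_id}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        write_gff3(annotations[strain], out / "gff" / f"{strain}.gff3")
    truth.to_json(out / "truth.json")
    if counts is not None:
        counts.to_csv(out / "nodule_counts.tsv", sep="\t", index=False)
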