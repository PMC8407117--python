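"""Canonical k-mer counting over strain genomes.

k-mers (default k=13) act as variant proxies capturing SNPs and indels
without a reference genome.  Each sliding window is collapsed to its
canonical form -- the lexicographically smaller of the window and its
reverse complement -- so assemblies of arbitrary strand orientation
yield identical profiles.  Counting is done on 2-bit integer codes
(A=0, C=1, G=2, T=3), so a 13-mer fits comfortably in an int64.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_K = 13

_BASES = "ACGT"

# 2-bit codes for unambiguous bases; -1 marks ambiguity codes (windows
# containing them are skipped); -2 marks characters outside IUPAC.
_CODE = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
for _b in "NRYSWKMBDHVU":  # IUPAC ambiguity codes (and U) -> skip window
    _CODE[ord(_b)] = -1
    _CODE[ord(_b.lower())] = -1


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide codes."""


def encode_sequence(seq: str, record_id: str = "<sequence>") -> np.ndarray:
    """Map a nucleotide string to int8 codes; ambiguity codes become -1."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    bad = np.nonzero(codes == -2)[0]
    if bad.size:
        off = int(bad[0])
        raise SequenceAlphabetError(
            f"non-IUPAC character {seq[off]!r} in record {record_id!r} at offset {off}"
        )
    return codes


def kmer_to_code(kmer: str) -> int:
    codes = encode_sequence(kmer, kmer)
    if (codes < 0).any():
        raise ValueError(f"k-mer {kmer!r} contains an ambiguous base")
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def canonical_code(code: int, k: int) -> int:
    """Canonical (strand-collapsed) form of a 2-bit k-mer code."""
    rc = 0
    c = code
    for _ in range(k):
        rc = (rc << 2) | (3 - (c & 3))
        c >>= 2
    return min(code, rc)


def canonicalize(kmer: str) -> str:
    """Canonical string form: min(kmer, reverse complement)."""
    k = len(kmer)
    return code_to_kmer(canonical_code(kmer_to_code(kmer), k), k)


def window_codes(seq: str, k: int = DEFAULT_K,
                 record_id: str = "<sequence>"
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Positional window codes of ``seq``.

    Returns ``(fwd, rev, clean)`` where ``fwd[i]`` / ``rev[i]`` are the
    2-bit codes of the forward window starting at offset i and of its
    reverse complement, and ``clean[i]`` marks windows free of
    ambiguity codes.  Empty arrays when the sequence is shorter than k.
    """
    codes = encode_sequence(seq, record_id)
    n = codes.size
    if n < k:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, np.empty(0, dtype=bool)
    valid = codes >= 0
    base = np.where(valid, codes, 0).astype(np.int64)
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.int64)
    rev = np.zeros(m, dtype=np.int64)
    for j in range(k):
        col = base[j:j + m]
        fwd = (fwd << 2) | col
        rev |= (3 - col) << (2 * j)
    bad = ~valid
    cum = np.concatenate(([0], np.cumsum(bad)))
    clean = (cum[k:] - cum[:-k]) == 0
    return fwd, rev, clean


def sequence_kmer_codes(seq: str, k: int = DEFAULT_K,
                        record_id: str = "<sequence>") -> np.ndarray:
    """Canonical codes of every valid window of ``seq``, in genome order.

    Windows containing an ambiguity code are dropped.  Returns an empty
    array when the sequence is shorter than k.
    """
    fwd, rev, clean = window_codes(seq, k, record_id)
    return np.minimum(fwd, rev)[clean]


@dataclass
class KmerPresenceMatrix:
    """Strain x canonical-k-mer count matrix.

    ``kmer_codes`` are sorted 2-bit codes; ``counts`` is a dense
    (n_strains, n_kmers) int32 array.  Presence means count >= 1.
    """

    strains: list[str]
    kmer_codes: np.ndarray
    counts: np.ndarray
    k: int = DEFAULT_K

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_kmers(self) -> int:
        return self.kmer_codes.size

    @property
    def presence(self) -> np.ndarray:
        return self.counts >= 1

    @property
    def kmers(self) -> list[str]:
        return [code_to_kmer(int(c), self.k) for c in self.kmer_codes]

    def presence_of(self, kmer: str) -> dict[str, bool]:
        code = canonical_code(kmer_to_code(kmer), self.k)
        idx = np.searchsorted(self.kmer_codes, code)
        if idx >= self.n_kmers or self.kmer_codes[idx] != code:
            return {s: False for s in self.strains}
        col = self.presence[:, idx]
        return {s: bool(col[i]) for i, s in enumerate(self.strains)}

    def carrier_sets(self) -> list[frozenset[str]]:
        """Per k-mer, the set of strains in which it is present."""
        strains = np.asarray(self.strains, dtype=object)
        return [frozenset(strains[self.presence[:, j]])
                for j in range(self.n_kmers)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts.T, index=pd.Index(self.kmers, name="kmer"),
                            columns=self.strains)


def count_kmers(genomes: Mapping[str, Mapping[str, str]],
                k: int = DEFAULT_K) -> KmerPresenceMatrix:
    """Count canonical k-mers per strain across all replicons.

    Parameters
    ----------
    genomes : mapping
        strain id -> (replicon id -> sequence).  Records shorter than k
        are skipped (they contribute no windows).
    """
    strains = list(genomes)
    per_strain: list[tuple[np.ndarray, np.ndarray]] = []
    for strain in strains:
        parts = [sequence_kmer_codes(seq, k, record_id=f"{strain}/{rec}")
                 for rec, seq in genomes[strain].items()]
        allc = (np.concatenate(parts) if parts
                else np.empty(0, dtype=np.int64))
        uniq, cnt = np.unique(allc, return_counts=True)
        per_strain.append((uniq, cnt))
    universe = np.unique(np.concatenate([u for u, _ in per_strain])) \
        if per_strain else np.empty(0, dtype=np.int64)
    counts = np.zeros((len(strains), universe.size), dtype=np.int32)
    for i, (uniq, cnt) in enumerate(per_strain):
        counts[i, np.searchsorted(universe, uniq)] = cnt
    return KmerPresenceMatrix(strains=strains, kmer_codes=universe,
                              counts=counts, k=k)


def filter_kmers(matrix: KmerPresenceMatrix, min_present: int = 2,
                 min_absent: int = 2) -> KmerPresenceMatrix:
    """Drop k-mers present in fewer than ``min_present`` strains or
    absent from fewer than ``min_absent`` (the "-min 2 -max 2" rule)."""
    pres = matrix.presence.sum(axis=0)
    keep = (pres >= min_present) & (matrix.n_strains - pres >= min_absent)
    return KmerPresenceMatrix(strains=list(matrix.strains),
                              kmer_codes=matrix.kmer_codes[keep],
                              counts=matrix.counts[:, keep], k=matrix.k)


def kmer_distance(matrix: KmerPresenceMatrix) -> pd.DataFrame:
    """Pairwise Jaccard distance between strain k-mer presence sets.

    d(i, j) = 1 - |K_i & K_j| / |K_i | K_j|, computed on the full
    (unfiltered) profiles.  Raises on a strain with no k-mers.
    """
    if matrix.n_strains < 2:
        raise ValueError("need at least two strains for a distance matrix")
    pres = matrix.presence
    sizes = pres.sum(axis=1).astype(np.int64)
    empty = [s for s, n in zip(matrix.strains, sizes) if n == 0]
    if empty:
        raise ValueError(f"strain(s) with zero k-mers: {empty}")
    inter = (pres.astype(np.int64) @ pres.T.astype(np.int64))
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore"):
        d = 1.0 - inter / union
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.strains, columns=matrix.strains)
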