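"""Nodule-occupancy phenotypes from per-plant nodule counts.

A competition assay inoculates each plant with a GFP-tagged tester
strain and an RFP-tagged reference strain; four weeks later every root
nodule is scored green (tester only), red (reference only) or mixed
(both).  Per-plant occupancy is the fraction of nodules in each colour
class; the phenotype of a (tester, reference) pair is the arithmetic
mean over the replicate plants, either of the single-occupancy fraction
alone or of single + mixed.  Testers are classed as good (> 60%),
medium (20-60%) or weak (< 20%) competitors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import svd

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["competition_id", "strain_id", "plant_id",
                 "n_green", "n_red", "n_mixed"]

MODES = ("single", "single_plus_mixed")


class MissingCellError(ValueError):
    """Every plant of a (strain, competition) cell was excluded."""


def validate_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Check a nodule-count table: required columns, non-negative counts,
    unique (strain, plant) within each competition."""
    missing = [c for c in COUNT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"count table misses columns: {missing}")
    t = table[COUNT_COLUMNS].copy()
    for c in ("n_green", "n_red", "n_mixed"):
        t[c] = pd.to_numeric(t[c])
        if (t[c] < 0).any():
            raise ValueError(f"negative counts in column {c}")
    dup = t.duplicated(["competition_id", "strain_id", "plant_id"])
    if dup.any():
        raise ValueError("duplicate (competition, strain, plant) rows")
    return t


def plant_occupancy(table: pd.DataFrame) -> pd.DataFrame:
    """Per-plant occupancy fractions f_green, f_red, f_mixed.

    Plants with zero nodules are excluded with a warning: occupancy is
    undefined for them, and treating them as zeros would bias means.
    """
    t = validate_counts(table)
    total = t[["n_green", "n_red", "n_mixed"]].sum(axis=1)
    zero = total == 0
    if zero.any():
        for _, r in t[zero].iterrows():
            logger.warning(
                "plant %s (strain %s, competition %s) produced no nodules; "
                "excluded", r["plant_id"], r["strain_id"], r["competition_id"])
        t = t[~zero].copy()
        total = total[~zero]
    t["f_green"] = t["n_green"] / total
    t["f_red"] = t["n_red"] / total
    t["f_mixed"] = t["n_mixed"] / total
    return t


@dataclass
class OccupancyMatrix:
    """Strain x competition mean-occupancy fractions in [0, 1]."""

    values: pd.DataFrame           # strains as rows, competitions as columns
    mode: str                      # 'single' or 'single_plus_mixed'
    n_plants: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("occupancy values must lie in [0, 1]")


def mean_occupancy(table: pd.DataFrame, mode: str = "single",
                   pooled: bool = False) -> OccupancyMatrix:
    """Mean occupancy per (strain, competition) cell.

    ``mode='single'`` averages f_green; ``'single_plus_mixed'`` averages
    f_green + f_mixed.  The default is the mean of per-plant ratios;
    ``pooled=True`` instead pools counts across plants (sensitivity
    analysis).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    t = plant_occupancy(table)
    if t.empty:
        raise MissingCellError("no plant with nodules in the whole table")
    if pooled:
        g = t.groupby(["strain_id", "competition_id"])
        num = g["n_green"].sum() + (g["n_mixed"].sum() if mode ==
                                    "single_plus_mixed" else 0)
        den = g[["n_green", "n_red", "n_mixed"]].sum().sum(axis=1)
        cell = num / den
    else:
        t["f"] = t["f_green"] + (t["f_mixed"] if mode == "single_plus_mixed"
                                 else 0)
        cell = t.groupby(["strain_id", "competition_id"])["f"].mean()
    values = cell.unstack("competition_id")
    n_plants = (t.groupby(["strain_id", "competition_id"])["plant_id"]
                .count().unstack("competition_id").reindex_like(values))
    all_cells = table.groupby(["strain_id", "competition_id"]).size()
    lost = all_cells.index.difference(cell.index)
    if len(lost):
        s, c = lost[0]
        raise MissingCellError(
            f"all plants excluded for strain {s!r}, competition {c!r}")
    return OccupancyMatrix(values=values, mode=mode, n_plants=n_plants)


def normalize_for_gwas(matrix: OccupancyMatrix | pd.DataFrame,
                       competition_id: str) -> pd.Series:
    """Phenotype vector in [0, 1] for one competition.

    Fractions pass through unchanged; percent-scale columns (any value
    > 1, as in published occupancy tables) are divided by 100.  Values
    above 100 are rejected.  Accepts an OccupancyMatrix or a plain
    strain x competition DataFrame.
    """
    is_occ = isinstance(matrix, OccupancyMatrix)
    values = matrix.values if is_occ else matrix
    if competition_id not in values.columns:
        raise KeyError(f"competition {competition_id!r} not in matrix")
    col = values[competition_id].astype(float)
    if (col > 100).any():
        raise ValueError(
            "occupancy values above 100 are neither fractions nor percent")
    if (col > 1).any():
        col = col / 100.0
    col.attrs["mode"] = matrix.mode if is_occ else "unknown"
    col.attrs["competition_id"] = competition_id
    return col


def classify_competitor(value: float) -> str:
    """good (> 0.60), medium ([0.20, 0.60]), weak (< 0.20).

    Both class boundaries belong to 'medium': good competitors are
    *above* 60% and weak ones *below* 20%.
    """
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ValueError(f"occupancy {value!r} outside [0, 1]")
    if value > 0.60:
        return "good"
    if value < 0.20:
        return "weak"
    return "medium"


def pca_strains(matrix: OccupancyMatrix):
    """PCA of strains on competition mean values (column-centered SVD).

    Returns ``(scores, loadings, explained_variance)``; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    Explained-variance fractions sum to 1 (or are all zero for a
    degenerate constant matrix).
    """
    v = matrix.values
    if v.isna().any().any():
        raise ValueError(
            "occupancy matrix has missing cells; impute or drop strains first")
    if v.shape[0] < 2 or v.shape[1] < 2:
        raise ValueError("PCA needs at least 2 strains and 2 competitions")
    x = v.to_numpy(dtype=float)
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = svd(xc, full_matrices=False)
    # fix sign: largest |loading| positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s ** 2
    tot = var.sum()
    explained = var / tot if tot > 0 else np.zeros_like(var)
    ncomp = s.size
    cols = [f"PC{j + 1}" for j in range(ncomp)]
    scores = pd.DataFrame(u * s, index=v.index, columns=cols)
    loadings = pd.DataFrame(vt.T, index=v.columns, columns=cols)
    return scores, loadings, explained


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from squared distances and group labels."""
    n = d2.shape[0]
    groups = np.unique(labels)
    g = groups.size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for lab in groups:
        mask = labels == lab
        ss_within += d2[mask][:, mask].sum() / (2.0 * mask.sum())
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(matrix: OccupancyMatrix | pd.DataFrame,
              groups: dict[str, str] | pd.Series,
              n_perm: int = 999, seed: int | None = None,
              metric: str = "euclidean") -> dict:
    """Permutational multivariate ANOVA of strain occupancy profiles.

    Euclidean distances between strain rows by default; pseudo-F =
    (SS_between/(g-1)) / (SS_within/(n-g)); p = (1 + #{F_perm >=
    F_obs}) / (1 + n_perm) with seeded label permutations.  With more
    than two groups, all pairwise tests are run as well and their
    p-values Bonferroni-corrected.
    """
    v = matrix.values if isinstance(matrix, OccupancyMatrix) else matrix
    labels = pd.Series(groups).reindex(v.index)
    if labels.isna().any():
        raise ValueError("every strain needs a group label")
    counts = labels.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("need >= 2 groups with >= 2 strains each")
    x = v.to_numpy(dtype=float)
    if metric == "euclidean":
        diff = x[:, None, :] - x[None, :, :]
        d2 = (diff ** 2).sum(axis=2)
    else:
        from scipy.spatial.distance import pdist, squareform
        d2 = squareform(pdist(x, metric=metric)) ** 2
    lab = labels.to_numpy()
    f_obs = _pseudo_f(d2, lab)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        f_p = _pseudo_f(d2, rng.permutation(lab))
        if f_p >= f_obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    out = {"F": float(f_obs), "p": float(p), "n_perm": int(n_perm),
           "groups": {str(k): int(c) for k, c in counts.items()}}
    if len(counts) > 2:
        pairs = []
        names = sorted(counts.index)
        m = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                sel = labels.isin([names[i], names[j]])
                sub = v.loc[sel]
                res = permanova(sub, labels[sel], n_perm=n_perm,
                                seed=None if seed is None else
                                seed + i * 1000 + j)
                pairs.append({"a": names[i], "b": names[j], "F": res["F"],
                              "p": res["p"],
                              "p_bonferroni": min(1.0, res["p"] * m)})
        out["pairwise"] = pairs
    return out
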