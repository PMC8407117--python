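"""Per-k-mer association testing with a weighted Welch two-sample t-test.

For each k-mer, strains are split into a "present" and an "absent"
group and the continuous phenotype (nodule occupancy in [0, 1]) is
compared between the groups.  GSC sample weights w_i enter through
weighted means, weighted variances and Kish effective sample sizes:

    W_g     = sum of w_i over group g
    mu_g    = sum w_i x_i / W_g
    n_eff,g = W_g^2 / sum w_i^2
    s_g^2   = [sum w_i (x_i - mu_g)^2] * n_eff,g / ((n_eff,g - 1) * W_g)
    t       = (mu_1 - mu_2) / sqrt(s_1^2/n_eff,1 + s_2^2/n_eff,2)

with Welch-Satterthwaite degrees of freedom on the per-group variance
contributions.  With equal weights this reduces exactly to the classic
Welch test.  The statistic is invariant to rescaling all weights.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .kmers import KmerPresenceMatrix

logger = logging.getLogger(__name__)

#: two-sided p-value reported when one group has zero variance but the
#: group means differ (the t statistic diverges)
P_UNDERFLOW = float(np.finfo(float).tiny)


def weighted_welch_test(values: np.ndarray, present: np.ndarray,
                        weights: np.ndarray) -> tuple[float, float, float]:
    """Weighted Welch two-sample t-test of present vs absent strains.

    Returns ``(t, df, p)``.  Raises ValueError if either group is empty
    or has effective size <= 1.
    """
    values = np.asarray(values, dtype=float)
    present = np.asarray(present, dtype=bool)
    weights = np.asarray(weights, dtype=float)
    if not present.any() or present.all():
        raise ValueError("both groups must be nonempty")
    t, df, p, ok = _vectorized_welch(values, present[None, :], weights)
    if not ok[0]:
        raise ValueError("group effective sample size <= 1")
    return float(t[0]), float(df[0]), float(p[0])


def _group_moments(P: np.ndarray, w: np.ndarray, x: np.ndarray):
    """Weighted moments for each row-mask in P (n_tests, n_strains)."""
    Pw = P.astype(float)
    W = Pw @ w
    Q = Pw @ (w * w)
    S1 = Pw @ (w * x)
    S2 = Pw @ (w * x * x)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu = S1 / W
        n_eff = W * W / Q
        ss = S2 - W * mu * mu          # sum w_i (x_i - mu)^2
        s2 = ss * n_eff / ((n_eff - 1.0) * W)
    return W, mu, n_eff, s2


def _vectorized_welch(x: np.ndarray, presence: np.ndarray, w: np.ndarray):
    """Welch statistics for many presence patterns at once.

    Returns (t, df, p, ok) arrays; ``ok`` is False where a group is
    empty or its effective size is <= 1 (those tests are skipped).
    Zero variance in both groups yields t=0, p=1 for equal means and a
    tiny-clamped p for unequal means.
    """
    P1 = presence
    P2 = ~presence
    _, mu1, ne1, s21 = _group_moments(P1, w, x)
    _, mu2, ne2, s22 = _group_moments(P2, w, x)
    ok = (P1.any(axis=1) & P2.any(axis=1) & (ne1 > 1.0) & (ne2 > 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        v1 = s21 / ne1
        v2 = s22 / ne2
        denom = np.sqrt(v1 + v2)
        delta = mu1 - mu2
        t = delta / denom
        df = (v1 + v2) ** 2 / (v1 ** 2 / (ne1 - 1.0) + v2 ** 2 / (ne2 - 1.0))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate: no variance anywhere
    novar = ok & ~(denom > 0)
    eq = novar & (np.abs(delta) <= 1e-12)
    ne = novar & ~eq
    with np.errstate(invalid="ignore"):
        t = np.where(eq, 0.0, t)
        p = np.where(eq, 1.0, p)
        t = np.where(ne, np.sign(delta) * np.inf, t)
        p = np.where(ne, P_UNDERFLOW, p)
        df = np.where(novar, np.nan, df)
    return t, df, p, ok


def run_association(matrix: KmerPresenceMatrix, phenotype: pd.Series,
                    weights: pd.Series, alpha: float = 0.05,
                    multiple_testing: str | None = None) -> pd.DataFrame:
    """Test every retained k-mer against the phenotype.

    Rows with p <= ``alpha`` are kept (raw p-values by default, no
    multiple-testing correction; pass ``multiple_testing='bh'`` for
    Benjamini-Hochberg on top).  The table is sorted by ascending p,
    ties by descending |t| then k-mer string, and carries columns
    kmer, t, df, p, n_present, n_absent, delta_mu, carrier_strains.
    """
    strains = list(matrix.strains)
    missing = [s for s in strains if s not in phenotype.index]
    if missing or len(phenotype) != len(strains):
        raise ValueError(
            f"phenotype strains do not match k-mer matrix (missing: {missing})")
    x = phenotype.reindex(strains).to_numpy(dtype=float)
    w = weights.reindex(strains).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(w).any():
        raise ValueError("phenotype/weights contain NaN for some strain")

    pres = matrix.presence.T  # (n_kmers, n_strains)
    t, df, p, ok = _vectorized_welch(x, pres, w)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("skipped %d k-mers with a degenerate group", n_skip)
    # group means for the report
    _, m1, _, _ = _group_moments(pres, w, x)
    _, m2, _, _ = _group_moments(~pres, w, x)
    delta = m1 - m2
    keep = ok & (p <= alpha)
    idx = np.nonzero(keep)[0]
    kmers = np.array(matrix.kmers, dtype=object)[idx]
    n_present = pres[idx].sum(axis=1)
    carrier = [";".join(sorted(np.array(strains, dtype=object)[pres[i]]))
               for i in idx]
    table = pd.DataFrame({
        "kmer": kmers,
        "t": t[idx],
        "df": df[idx],
        "p": p[idx],
        "n_present": n_present.astype(int),
        "n_absent": (len(strains) - n_present).astype(int),
        "delta_mu": delta[idx],
        "carrier_strains": carrier,
    })
    if multiple_testing == "bh" and len(table):
        m = len(table)
        order = np.argsort(table["p"].to_numpy(), kind="stable")
        ranked = table["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        qvals = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(qvals, 1.0)
        table["q"] = q
        table = table[table["q"] <= alpha].copy()
    table = table.sort_values(
        ["p", "t", "kmer"], ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "t" else col,
        kind="stable").reset_index(drop=True)
    return table


def association_summary(table: pd.DataFrame) -> dict:
    """Headline numbers: total retained k-mers and the p-value range."""
    if len(table) == 0:
        return {"total_kmers": 0, "p_min": None, "p_max": None}
    return {"total_kmers": int(len(table)),
            "p_min": float(table["p"].min()),
            "p_max": float(table["p"].max())}


def select_best_kmers(table: pd.DataFrame, p_cut: float,
                      carrier_set: set[str] | frozenset[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """k-mers at p <= ``p_cut`` and, optionally, those whose carrier set
    exactly equals ``carrier_set`` (the "present exactly in the top
    competitors" selection).

    Returns ``(best, exact)`` data frames; ``exact`` is empty when no
    carrier set is given.
    """
    best = table[table["p"] <= p_cut].copy()
    if carrier_set is None:
        exact = best.iloc[0:0].copy()
    else:
        want = ";".join(sorted(carrier_set))
        exact = best[best["carrier_strains"] == want].copy()
    return best, exact
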