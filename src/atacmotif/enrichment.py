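"""Preranked gene-set enrichment over genomic regions, plus a
hypergeometric over-representation test.

Regions (ACS) are ranked by accessibility log2 fold-change; for each motif
the set of regions carrying a match is tested with the weighted
Kolmogorov-Smirnov running-sum statistic: walking down the ranking, member
hits add their weighted rank value and misses subtract a constant, and the
enrichment score (ES) is the signed extremum of the walk.  Significance
comes from a permutation null of random member sets of the same size drawn
from the same ranking; the normalized enrichment score (NES) divides ES by
the mean |null ES| of the same sign.  P-values are one-sided per ES sign,
normalized by the same-sign null count so a null set's p-value is uniform
on (0, 1], never zero (floor about 2/(n_perm + 2)), and Benjamini-Hochberg
adjusted across sets.

Ties in the ranking are broken by stable input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .differential import bh_adjust


def enrichment_score(ranked_values, membership, weight_exponent: float = 1.0
                     ) -> tuple[float, int]:
    """ES of a member set along a descending ranking, with extremum position.

    ``ranked_values`` are real values sorted descending; ``membership`` is
    0/1 per item.  Hits add ``|r|**w / sum_members |r|**w``; misses
    subtract ``1 / (n - n_members)``.  Returns (ES, 0-based position of
    the walk extremum).
    """
    r = np.asarray(ranked_values, dtype=float)
    mem = np.asarray(membership, dtype=bool)
    n = len(r)
    k = int(mem.sum())
    if k == 0 or k == n:
        raise ValueError("set must contain >=1 member and >=1 non-member")
    absr = np.abs(r) ** weight_exponent
    hit_cum = np.cumsum(np.where(mem, absr, 0.0))
    total = hit_cum[-1]
    if total > 0:
        hit_frac = hit_cum / total
    else:  # all member weights zero: fall back to equal hit mass
        hit_frac = np.cumsum(np.where(mem, 1.0, 0.0)) / k
    miss_cum = np.cumsum(~mem)
    walk = hit_frac - miss_cum / (n - k)
    i_max = int(np.argmax(walk))
    i_min = int(np.argmin(walk))
    if walk[i_max] >= -walk[i_min]:
        return float(walk[i_max]), i_max
    return float(walk[i_min]), i_min


def _es_from_positions(pos: np.ndarray, absr: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for many member sets given sorted member positions.

    ``pos`` is (n_sets, k) of ascending 0-based ranking positions; the walk
    between hits is linear, so extrema occur only just after a hit (maxima)
    or just before one (minima).
    """
    m, k = pos.shape
    h = absr[pos]
    H = np.cumsum(h, axis=1)
    H_prev = np.column_stack([np.zeros(m), H[:, :-1]])
    tot = H[:, -1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        Hn = np.where(tot > 0, H / tot, np.arange(1, k + 1) / k)
        Hn_prev = np.where(tot > 0, H_prev / tot, np.arange(0, k) / k)
    i = np.arange(1, k + 1)
    after = Hn - (pos + 1 - i) / (n - k)
    before = Hn_prev - (pos - (i - 1)) / (n - k)
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    return np.where(hi >= -lo, hi, lo)


@dataclass
class EnrichmentResult:
    set_id: str
    es: float
    nes: float
    p_value: float
    adj_p: float
    set_size: int
    leading_edge_size: int


def gsea_permutation(ranking: pd.Series, sets: dict, n_perm: int = 10000,
                     seed: int = 0, min_size: int = 5, max_size: int = 5000,
                     weight_exponent: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA for every set against one ranking.

    ``ranking`` maps item id -> real value (any order; sorted descending
    internally with stable ties).  ``sets`` maps set_id -> iterable of
    member ids; members absent from the ranking are ignored, and sets
    falling outside [min_size, max_size] after intersection are dropped
    with a warning.  The null for a set of size k is the ES of random
    k-subsets of the ranking; nulls are shared between sets of equal size.
    Deterministic given ``seed``.
    """
    order = np.argsort(-ranking.to_numpy(dtype=float), kind="stable")
    values = ranking.to_numpy(dtype=float)[order]
    item_pos = {item: i for i, item in enumerate(ranking.index[order])}
    n = len(values)
    absr = np.abs(values) ** weight_exponent

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for set_id, members in sets.items():
        pos = sorted(item_pos[m] for m in set(members) if m in item_pos)
        k = len(pos)
        if k < min_size or k > max_size or k == n:
            warnings.warn(f"set {set_id!r} dropped (size {k} after intersection)")
            continue
        es, extremum = enrichment_score(
            values, np.isin(np.arange(n), pos), weight_exponent)
        if k not in null_cache:
            nulls = np.empty(n_perm)
            chunk = max(1, min(n_perm, 5_000_000 // max(n, 1)))
            done = 0
            while done < n_perm:
                m_chunk = min(chunk, n_perm - done)
                keys = rng.random((m_chunk, n))
                perm = np.argpartition(keys, k, axis=1)[:, :k]
                perm.sort(axis=1)
                nulls[done:done + m_chunk] = _es_from_positions(perm, absr, n)
                done += m_chunk
            null_cache[k] = nulls
        null = null_cache[k]
        same_sign = null > 0 if es >= 0 else null < 0
        exceed = int(np.sum(same_sign & (np.abs(null) >= abs(es))))
        # one-sided per ES sign, normalized by the same-sign null count so
        # a null set's p is uniform on (0, 1]
        p = (1 + exceed) / (1 + int(same_sign.sum()))
        denom = np.abs(null[same_sign]).mean() if same_sign.any() \
            else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        pos_arr = np.asarray(pos)
        if es >= 0:
            leading = int(np.sum(pos_arr <= extremum))
        else:
            leading = int(np.sum(pos_arr >= extremum))
        rows.append((set_id, k, es, nes, p, leading))
    df = pd.DataFrame(rows, columns=["set_id", "set_size", "es", "nes",
                                     "p_value", "leading_edge_size"])
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy()) if len(df) else []
    return df.set_index("set_id")[
        ["set_size", "es", "nes", "p_value", "adj_p", "leading_edge_size"]]


def hypergeometric_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` successes among ``n`` draws from a universe of ``N`` items of
    which ``K`` are successes.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent hypergeometric arguments "
                         f"k={k}, K={K}, n={n}, N={N}")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def sets_from_match_matrix(match_matrix) -> dict:
    """Motif -> member-ACS sets from a MotifMatchMatrix (N > 0)."""
    N = match_matrix.N
    return {m: list(N.index[N[m] > 0]) for m in N.columns}


def read_sets(path) -> dict:
    """Read a GMT-like file: ``set_id<TAB>member<TAB>member...`` per line."""
    out = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                out[parts[0]] = [p for p in parts[1:] if p]
    return out


def write_sets(sets: dict, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for set_id, members in sets.items():
            fh.write("\t".join([set_id, *map(str, members)]) + "\n")


class PrerankedGSEA:
    """Model object: a ranking plus the membership sets to test against it.

    The usual ranking is the accessibility log2 fold-change of the
    significantly changing ACS; sets are the ACS carrying each motif.
    """

    def __init__(self, ranking: pd.Series, sets: dict,
                 min_size: int = 5, max_size: int = 5000,
                 weight_exponent: float = 1.0):
        if ranking.index.duplicated().any():
            raise ValueError("duplicate ids in ranking")
        self.ranking = ranking.astype(float)
        self.sets = dict(sets)
        self.min_size = min_size
        self.max_size = max_size
        self.weight_exponent = weight_exponent

    def fit(self, n_perm: int = 10000, seed: int = 0) -> "GSEAResults":
        table = gsea_permutation(
            self.ranking, self.sets, n_perm=n_perm, seed=seed,
            min_size=self.min_size, max_size=self.max_size,
            weight_exponent=self.weight_exponent)
        return GSEAResults(self, table.sort_values("p_value"), n_perm, seed)


@dataclass
class GSEAResults:
    model: PrerankedGSEA
    table: pd.DataFrame
    n_perm: int
    seed: int

    def significant(self, adj_p: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adj_p"] < adj_p]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            f"Preranked GSEA: {len(self.table)} sets, ranking of "
            f"{len(self.model.ranking)} items, {self.n_perm} permutations",
            f"  significant at adj_p < 0.05: {len(sig)}",
        ]
        for set_id, row in sig.head(10).iterrows():
            lines.append(f"    {set_id}: NES={row['nes']:+.2f} "
                         f"adj_p={row['adj_p']:.2g}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="set_id", lineterminator="\n")
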