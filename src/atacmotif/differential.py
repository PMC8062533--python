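"""Differential chromatin accessibility between two groups of samples.

The model follows the standard negative-binomial count framework for
replicated ATAC-seq/RNA-seq style data: per-sample library sizes with TMM
(trimmed mean of M-values) normalization factors, a common dispersion
``phi`` shared by all sites (variance ``mu + phi * mu**2``), an exact
conditional test on the group sums for each accessible chromatin site
(ACS), Benjamini-Hochberg FDR adjustment, and classification of each ACS
as Up (more accessible in the treatment group, e.g. adult), Down (more
accessible in the reference group, e.g. P10) or Stable.

Entry point: :class:`DifferentialAccessibility` (a model object built from
a count matrix), whose :meth:`~DifferentialAccessibility.fit` returns a
:class:`DifferentialResults` with the per-site table and a ``summary()``.
The individual steps (``tmm_factors``, ``estimate_common_dispersion``,
``nb_exact_test``...) are importable functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DISPERSION_BOUNDS = (1e-6, 10.0)


# ---------------------------------------------------------------------------
# normalization


def _upper_quartiles(counts: np.ndarray, lib_sizes: np.ndarray) -> np.ndarray:
    return np.percentile(counts / lib_sizes, 75, axis=0)


def tmm_factors(counts: pd.DataFrame | np.ndarray, ref_sample=None) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    For each sample against the reference, M (log ratio) and A (log
    abundance) values are computed on features expressed in both; the M
    values are trimmed 30% on each side and the A values 5% on each side,
    and the factor is the exponentiated inverse-variance-weighted mean of
    the surviving M values.  The reference defaults to the sample whose
    upper-quartile expression is closest to the mean upper-quartile.
    """
    if isinstance(counts, pd.DataFrame):
        y = counts.to_numpy(dtype=float)
        samples = list(counts.columns)
    else:
        y = np.asarray(counts, dtype=float)
        samples = list(range(y.shape[1]))
    if y.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = y.sum(axis=0)
    if (lib == 0).any():
        bad = [samples[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    uq = _upper_quartiles(y, lib)
    if ref_sample is None:
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = samples.index(ref_sample)
    factors = np.ones(y.shape[1])
    for k in range(y.shape[1]):
        if k == ref:
            continue
        factors[k] = _tmm_pair(y[:, k], y[:, ref], lib[k], lib[ref])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(yk: np.ndarray, yr: np.ndarray, nk: float, nr: float) -> float:
    keep = (yk > 0) & (yr > 0)
    yk, yr = yk[keep], yr[keep]
    if len(yk) == 0:
        return 1.0
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    # variance of M from the delta method; weight is its inverse
    v = (nk - yk) / (nk * yk) + (nr - yr) / (nr * yr)
    if np.allclose(m, m[0], atol=1e-10):
        return float(2 ** m[0])
    m_lo, m_hi = np.quantile(m, [0.30, 0.70])
    a_lo, a_hi = np.quantile(a, [0.05, 0.95])
    keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not keep.any():
        return 1.0
    w = 1.0 / np.maximum(v[keep], 1e-12)
    return float(2 ** (np.sum(w * m[keep]) / np.sum(w)))


@dataclass
class NormalizationState:
    """Library sizes, TMM factors (geometric mean 1) and common dispersion."""

    sample_ids: list
    lib_sizes: np.ndarray
    tmm_factors: np.ndarray
    dispersion: float = float("nan")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.tmm_factors


def equalize_counts(counts: np.ndarray, effective_libs: np.ndarray) -> np.ndarray:
    """Scale counts to the geometric-mean effective library and round.

    This puts every sample on a common library size so group sums can be
    compared by the conditional exact test (an approximation to full
    quantile adjustment).
    """
    target = np.exp(np.mean(np.log(effective_libs)))
    scaled = counts * (target / effective_libs)[None, :]
    return np.rint(scaled).astype(np.int64)


# ---------------------------------------------------------------------------
# dispersion


def _conditional_loglik(y: np.ndarray, group_cols: list[np.ndarray], phi: float) -> float:
    """NB log-likelihood conditional on each site's group total.

    Conditioning on the within-group sums eliminates the per-site group
    means (the qCML device), avoiding the downward bias of profile maximum
    likelihood at n = 3 per group.
    """
    r = 1.0 / phi
    ll = 0.0
    for cols in group_cols:
        yg = y[:, cols]
        n = yg.shape[1]
        z = yg.sum(axis=1)
        ll += float(
            gammaln(yg + r).sum()
            - gammaln(z + n * r).sum()
            + len(z) * gammaln(n * r)
            - len(z) * n * gammaln(r)
        )
    return ll


def estimate_common_dispersion(counts, groups, factors=None, tol: float = 1e-4) -> float:
    """Common NB dispersion phi maximizing the conditional likelihood.

    Counts are first scaled to a common effective library; phi is found by
    golden-section search on log(phi) within ``[1e-6, 10]``.
    """
    y, samples = _as_matrix(counts)
    lib = y.sum(axis=0)
    if factors is None:
        factors = np.ones(len(samples))
    yq = equalize_counts(y, lib * np.asarray(factors))
    labels = _group_labels(groups, samples)
    group_cols = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    group_cols = [c for c in group_cols if len(c) >= 2]
    if not group_cols:
        raise ValueError("dispersion estimation needs a group with >= 2 samples")
    informative = np.zeros(yq.shape[0], dtype=bool)
    for cols in group_cols:
        informative |= yq[:, cols].sum(axis=1) > 0
    if not informative.any():
        warnings.warn("all sites empty; returning lower dispersion bound")
        return DISPERSION_BOUNDS[0]
    yq = yq[informative]

    lo, hi = np.log(DISPERSION_BOUNDS[0]), np.log(DISPERSION_BOUNDS[1])
    invphi = (np.sqrt(5) - 1) / 2

    def f(logphi: float) -> float:
        return -_conditional_loglik(yq, group_cols, float(np.exp(logphi)))

    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while (b - a) > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    phi = float(np.exp((a + b) / 2))
    if phi <= DISPERSION_BOUNDS[0] * 1.5 and f(lo) <= min(fc, fd):
        phi = DISPERSION_BOUNDS[0]
    return phi


# ---------------------------------------------------------------------------
# exact test


def nb_exact_test(counts_a: np.ndarray, counts_b: np.ndarray, phi: float) -> np.ndarray:
    """Exact conditional two-sided NB test per site.

    ``counts_a`` and ``counts_b`` are (sites x replicates) matrices on
    equal effective libraries.  Conditional on the total ``t`` of the two
    group sums, the split follows a distribution free of the common mean;
    the two-sided p-value sums the probabilities of all splits no more
    probable than the observed one.  At ``phi = 0`` this is the conditional
    Binomial(t, n_a / (n_a + n_b)) test.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a))
    counts_b = np.atleast_2d(np.asarray(counts_b))
    if (counts_a < 0).any() or (counts_b < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    za = counts_a.sum(axis=1).astype(np.int64)
    zb = counts_b.sum(axis=1).astype(np.int64)
    out = np.ones(len(za))
    for i, (a_obs, t) in enumerate(zip(za, za + zb)):
        if t == 0:
            continue
        a = np.arange(t + 1)
        if phi == 0:
            logf = sps.binom.logpmf(a, t, n_a / (n_a + n_b))
        else:
            ra, rb = n_a / phi, n_b / phi
            logf = (gammaln(a + ra) - gammaln(a + 1)
                    + gammaln(t - a + rb) - gammaln(t - a + 1))
            logf -= logsumexp(logf)
        obs = logf[a_obs]
        p = float(np.exp(logsumexp(logf[logf <= obs + 1e-10])))
        out[i] = min(p, 1.0)
    return out


# ---------------------------------------------------------------------------
# effect size, adjustment, classification


def log2_fold_change(counts, factors, groups, treatment, reference,
                     prior_count: float = 0.5) -> np.ndarray:
    """Per-site log2 fold-change (treatment minus reference).

    Group means of normalized counts are augmented by a prior count (scaled
    by relative effective library size) before taking the ratio, so sites
    with zero counts have a finite, shrunken fold-change.
    """
    y, samples = _as_matrix(counts)
    labels = _group_labels(groups, samples)
    eff = y.sum(axis=0) * np.asarray(factors, dtype=float)
    prior = prior_count * eff / eff.mean()
    norm = (y + prior[None, :]) / eff[None, :]
    m_t = norm[:, labels == treatment].mean(axis=1)
    m_r = norm[:, labels == reference].mean(axis=1)
    return np.log2(m_t / m_r)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_acs(table: pd.DataFrame, p_threshold: float = 0.05,
                 fdr_threshold: float = 0.2) -> pd.Series:
    """Assign Up / Down / Stable per site from log2fc, p_value and fdr."""
    sig = (table["p_value"] < p_threshold) & (table["fdr"] < fdr_threshold)
    cls = np.where(sig & (table["log2fc"] > 0), "Up",
                   np.where(sig & (table["log2fc"] < 0), "Down", "Stable"))
    return pd.Series(cls, index=table.index, name="class")


# ---------------------------------------------------------------------------
# model / results


def _as_matrix(counts) -> tuple[np.ndarray, list]:
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), list(counts.columns)
    y = np.asarray(counts, dtype=float)
    return y, list(range(y.shape[1]))


def _group_labels(groups, samples) -> np.ndarray:
    if isinstance(groups, pd.Series):
        return groups.reindex(samples).to_numpy()
    if isinstance(groups, dict):
        return np.asarray([groups[s] for s in samples])
    return np.asarray(list(groups))


class DifferentialAccessibility:
    """Two-group NB model of per-site accessibility counts.

    Parameters
    ----------
    counts : DataFrame (sites x samples) of non-negative integers.
    groups : mapping or Series sample -> group label (exactly two labels).
    reference, treatment : which label is the baseline (e.g. "P10") and
        which the contrast (e.g. "adult"); positive log2 fold-changes mean
        more accessible in the treatment group.  When omitted and the
        labels are {"P10", "adult"}, P10 is the reference; otherwise the
        lexicographically smaller label is.
    """

    def __init__(self, counts: pd.DataFrame, groups, reference=None, treatment=None):
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(np.asarray(counts))
        self.counts = counts
        self.samples = list(counts.columns)
        self.labels = _group_labels(groups, self.samples)
        uniq = sorted(set(self.labels))
        if len(uniq) != 2:
            raise ValueError(f"need exactly two groups, got {uniq}")
        if reference is None and treatment is None and set(uniq) == {"P10", "adult"}:
            reference, treatment = "P10", "adult"
        self.reference = reference if reference is not None else uniq[0]
        self.treatment = treatment if treatment is not None else \
            next(g for g in uniq if g != self.reference)
        if {self.reference, self.treatment} != set(uniq):
            raise ValueError("reference/treatment do not match the group labels")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs):
        """Build from a counts TSV and a sample sheet TSV (sample, group)."""
        from .formats import read_counts_table

        counts = read_counts_table(counts_path)
        sheet = pd.read_csv(samples_path, sep="\t")
        groups = dict(zip(sheet["sample"], sheet["group"]))
        return cls(counts, groups, **kwargs)

    def fit(self, p_threshold: float = 0.05, fdr_threshold: float = 0.2,
            prior_count: float = 0.5, dispersion: float | None = None
            ) -> "DifferentialResults":
        """Normalize, estimate dispersion, test every site and classify."""
        y = self.counts.to_numpy(dtype=float)
        factors = tmm_factors(self.counts)
        lib = y.sum(axis=0)
        norm = NormalizationState(self.samples, lib, factors)
        if dispersion is None:
            dispersion = estimate_common_dispersion(self.counts, self.labels, factors)
        norm.dispersion = dispersion
        yq = equalize_counts(y, norm.effective_lib_sizes)
        is_t = self.labels == self.treatment
        p = nb_exact_test(yq[:, is_t], yq[:, ~is_t], dispersion)
        fc = log2_fold_change(self.counts, factors, self.labels,
                              self.treatment, self.reference, prior_count)
        table = pd.DataFrame(
            {"log2fc": fc, "p_value": p, "fdr": bh_adjust(p)},
            index=self.counts.index.rename("acs_id"),
        )
        table["class"] = classify_acs(table, p_threshold, fdr_threshold)
        return DifferentialResults(self, table, norm, p_threshold, fdr_threshold)


@dataclass
class DifferentialResults:
    """Fitted per-site differential accessibility."""

    model: DifferentialAccessibility
    table: pd.DataFrame  # log2fc, p_value, fdr, class per site
    normalization: NormalizationState
    p_threshold: float
    fdr_threshold: float

    @property
    def class_fractions(self) -> pd.Series:
        frac = self.table["class"].value_counts(normalize=True)
        return frac.reindex(["Up", "Down", "Stable"], fill_value=0.0)

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["class"] != "Stable"]

    def summary(self) -> str:
        n = len(self.table)
        f = self.class_fractions
        lines = [
            "Differential accessibility (NB exact test, common dispersion)",
            f"  sites: {n}   contrast: {self.model.treatment} vs {self.model.reference}",
            f"  common dispersion: {self.normalization.dispersion:.4g}",
            "  TMM factors: " + ", ".join(
                f"{s}={v:.3f}" for s, v in
                zip(self.normalization.sample_ids, self.normalization.tmm_factors)),
            f"  thresholds: p < {self.p_threshold}, FDR < {self.fdr_threshold}",
            f"  Up: {f['Up']:.1%}   Down: {f['Down']:.1%}   Stable: {f['Stable']:.1%}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="acs_id", lineterminator="\n")

    def plot_volcano(self, ax=None):
        """Volcano plot: log2FC vs -log10 FDR, colored by class."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        colors = {"Up": "tab:green", "Down": "tab:red", "Stable": "tab:blue"}
        for cls, sub in self.table.groupby("class"):
            ax.scatter(sub["log2fc"], -np.log10(sub["fdr"].clip(lower=1e-300)),
                       s=4, alpha=0.5, label=cls, color=colors.get(cls, "grey"))
        ax.set_xlabel("log2 fold-change")
        ax.set_ylabel("-log10 FDR")
        ax.legend(markerscale=3)
        return ax
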