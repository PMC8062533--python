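"""PWM scanning with exact score-distribution p-values.

A position frequency matrix is converted to a log-odds position-specific
scoring matrix (PSSM) against a 0-order background.  The null distribution
of the score of a random background word is computed exactly by dynamic
programming, giving a p-value for every attainable score; sequences are
then scanned on both strands and windows with ``p <= threshold_p`` are
reported, FIMO-style.

The dynamic programme convolves the per-position score distributions as a
sparse distribution over the *distinct attainable scores* (merging exact
ties), so p-values agree with exhaustive word enumeration to floating
point precision.  Only when a motif's attainable-score set grows beyond a
cap (wide motifs with many distinct column values) does it fall back to a
fixed-granularity integer grid.  Windows containing the ambiguity code N
are excluded.  Backgrounds are symmetrized over complementary bases so
the null distribution is strand-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import ALPHABET, PWM

# Row order A, C, G, T; index 4 is reserved for N in encoded sequences.
_CODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_MAX_EXACT_STATES = 2_000_000   # sparse-DP state cap before grid fallback
_GRID_BINS = 1_000_000          # grid granularity in fallback mode
# Score assigned to N cells (and -inf cells in window scoring): low enough
# that no window containing one can ever reach a match threshold.
_N_SCORE = -1e30
_SCORE_TOL = 1e-9               # tie tolerance for float score comparisons


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN (case-insensitive) as integers 0..4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def symmetrize_background(background: np.ndarray) -> np.ndarray:
    """Average a 0-order background with its complement (A<->T, C<->G)."""
    b = np.asarray(background, dtype=float)
    return (b + b[::-1]) / 2.0


def empirical_background(sequences) -> np.ndarray:
    """Symmetrized mononucleotide composition of a sequence collection (N ignored)."""
    counts = np.zeros(4, dtype=float)
    for s in sequences:
        codes = encode_sequence(s)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return symmetrize_background(counts / counts.sum())


@dataclass
class PSSM:
    """Log-odds scoring matrix (log2 units) with its background model."""

    motif_id: str
    scores: np.ndarray  # 4 x width, may contain -inf when pseudocount == 0
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.motif_id, self.scores[::-1, ::-1].copy(),
                    self.background, self.pseudocount)

    def max_score(self) -> float:
        return float(self.scores.max(axis=0).sum())


def pfm_to_pssm(pwm: PWM, background=None, pseudocount: float = 0.1) -> PSSM:
    """Convert a PFM to a log2-odds PSSM.

    The pseudocount is distributed over bases proportionally to the
    background: ``prob[b,j] = (count[b,j] + pc * bg[b]) / (total_j + pc)``.
    A zero pseudocount is allowed only when no column total is zero;
    resulting zero probabilities score ``-inf`` (such windows can never
    match).
    """
    if background is None:
        background = np.full(4, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    bg = bg / bg.sum()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.asarray(pwm.matrix, dtype=float)
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("zero column total requires a positive pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    with np.errstate(divide="ignore"):
        scores = np.log2(probs / bg[:, None])
    return PSSM(pwm.id, scores, bg, pseudocount)


class ScoreDistribution:
    """Exact null distribution of PSSM scores for random background words.

    The per-position score distributions are convolved left to right as a
    sparse distribution over distinct float scores, merging exact ties, so
    ``P(score >= s)`` is exact.  Words containing a ``-inf`` cell score
    below every finite score and are counted only at ``p(-inf) = 1``.
    Motifs whose distinct-score state space exceeds the cap are handled on
    an integer grid instead (granularity ``(max - min) / 1e6``), in which
    case cell scores are grid-rounded consistently for both the null and
    window scoring.
    """

    def __init__(self, pssm: PSSM, max_states: int = _MAX_EXACT_STATES):
        self.pssm = pssm
        scores = np.asarray(pssm.scores, dtype=float)
        finite = np.isfinite(scores)
        self.exact = True
        # cell_values: the scores actually summed over windows; -inf / N
        # cells get _N_SCORE so such windows can never match
        self.cell_values = np.where(finite, scores, _N_SCORE)
        if not self._build_sparse(scores, finite, pssm.background, max_states):
            self.exact = False
            self._build_grid(scores, finite, pssm.background)

    # -- sparse exact DP ---------------------------------------------------

    def _build_sparse(self, scores, finite, bg, max_states: int) -> bool:
        vals = np.array([0.0])
        probs = np.array([1.0])
        for j in range(scores.shape[1]):
            col = scores[finite[:, j], j]
            colp = np.asarray(bg)[finite[:, j]]
            cv, inv = np.unique(col, return_inverse=True)
            cp = np.bincount(inv, weights=colp)
            # accumulated + column value: same left-to-right addition order
            # as window scoring, so attainable scores match bit for bit
            new = (vals[:, None] + cv[None, :]).ravel()
            newp = (probs[:, None] * cp[None, :]).ravel()
            vals, inv = np.unique(new, return_inverse=True)
            probs = np.bincount(inv, weights=newp)
            if len(vals) > max_states:
                return False
        self._values = vals  # ascending
        # survival[i] = P(score >= values[i]) over finite-score words
        self._survival = probs[::-1].cumsum()[::-1]
        self._dead_mass = max(0.0, 1.0 - float(probs.sum()))
        return True

    # -- grid fallback -----------------------------------------------------

    def _build_grid(self, scores, finite, bg) -> None:
        col_min = np.where(finite, scores, np.inf).min(axis=0)
        col_max = np.where(finite, scores, -np.inf).max(axis=0)
        span = float(col_max.sum() - col_min.sum())
        g = max(span / _GRID_BINS, 1e-12)
        ints = np.rint(np.where(finite, scores, 0.0) / g).astype(np.int64)
        lo = int(np.where(finite, ints, 2**62).min(axis=0).sum())
        hi = int(np.where(finite, ints, -(2**62)).max(axis=0).sum())
        cur = np.array([1.0])
        cur_lo = 0
        for j in range(scores.shape[1]):
            fj = finite[:, j]
            c_lo, c_hi = int(ints[fj, j].min()), int(ints[fj, j].max())
            nxt = np.zeros(len(cur) + c_hi - c_lo, dtype=float)
            for b in range(4):
                if not fj[b]:
                    continue
                off = int(ints[b, j]) - c_lo
                nxt[off : off + len(cur)] += cur * bg[b]
            cur = nxt
            cur_lo += c_lo
        dist = np.zeros(hi - lo + 1, dtype=float)
        dist[cur_lo - lo : cur_lo - lo + len(cur)] = cur
        self._values = (np.arange(lo, hi + 1)) * g
        self._survival = dist[::-1].cumsum()[::-1]
        self._dead_mass = max(0.0, 1.0 - float(cur.sum()))
        # grid-rounded cell scores keep window sums on the same lattice
        self.cell_values = np.where(finite, ints * g, _N_SCORE)

    # -- queries -----------------------------------------------------------

    def pvalue(self, score) -> float | np.ndarray:
        """P(score of a random background word >= score), exact ties included."""
        s = np.asarray(score, dtype=float)
        idx = np.searchsorted(self._values, s - _SCORE_TOL, side="left")
        p = np.where(idx < len(self._survival),
                     self._survival[np.minimum(idx, len(self._survival) - 1)], 0.0)
        p = np.where(s <= self._values[0] - _SCORE_TOL,
                     self._survival[0] + self._dead_mass, p)
        p = np.minimum(p, 1.0)
        return p if p.ndim else float(p)

    def score_threshold(self, threshold_p: float) -> float:
        """Smallest attainable score whose p-value is <= threshold_p."""
        idx = np.searchsorted(-self._survival, -threshold_p, side="left")
        if idx >= len(self._values):
            return np.inf  # unattainable: nothing reaches the threshold
        return float(self._values[idx])

    def min_score(self) -> float:
        return float(self._values[0])

    def max_score(self) -> float:
        return float(self._values[-1])


def score_distribution(pssm: PSSM) -> ScoreDistribution:
    """Exact p-value function over scores (see :class:`ScoreDistribution`)."""
    return ScoreDistribution(pssm)


def _window_scores(codes: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Score of every window, summed left to right; N cells poison the window."""
    w = cells.shape[1]
    n_win = len(codes) - w + 1
    if n_win <= 0:
        return np.zeros(0)
    padded = np.vstack([cells, np.full(w, _N_SCORE)])
    out = np.zeros(n_win)
    for j in range(w):
        out += padded[codes[j : j + n_win], j]
    return out


@dataclass
class MotifMatch:
    motif_id: str
    offset: int  # 0-based, + strand coordinate of the window start
    strand: str
    score: float
    p_value: float


def scan_sequence(pssm: PSSM, sequence: str, threshold_p: float = 1e-4,
                  dist: ScoreDistribution | None = None) -> list[MotifMatch]:
    """Report every window on either strand with ``p(score) <= threshold_p``.

    Offsets are 0-based positions of the window start on the + strand;
    windows containing N are skipped.  Sequences shorter than the motif
    yield an empty list.
    """
    if dist is None:
        dist = score_distribution(pssm)
    codes = encode_sequence(sequence)
    thr = dist.score_threshold(threshold_p)
    matches: list[MotifMatch] = []
    for strand, cells in (("+", dist.cell_values),
                          ("-", dist.cell_values[::-1, ::-1])):
        win = _window_scores(codes, cells)
        for off in np.flatnonzero(win >= thr - _SCORE_TOL):
            s = float(win[off])
            matches.append(MotifMatch(pssm.motif_id, int(off), strand,
                                      s, float(dist.pvalue(s))))
    matches.sort(key=lambda m: (m.offset, m.strand))
    return matches


@dataclass
class MotifMatchMatrix:
    """ACS x motif match matrix ``N`` at a scan p-value threshold.

    ``N`` is binary by default (1 iff the motif has at least one match in
    the ACS); count mode stores the number of matches.
    """

    N: pd.DataFrame  # rows = ACS ids, columns = motif ids
    threshold_p: float
    mode: str = "binary"

    @property
    def acs_ids(self):
        return list(self.N.index)

    @property
    def motif_ids(self):
        return list(self.N.columns)

    def to_tsv(self, path) -> None:
        self.N.to_csv(path, sep="\t", index_label="acs_id", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path, threshold_p: float = float("nan"), mode: str = "binary"):
        N = pd.read_csv(path, sep="\t", index_col="acs_id")
        return cls(N=N, threshold_p=threshold_p, mode=mode)


def build_match_matrix(acs_sequences, pssms, threshold_p: float = 1e-4,
                       mode: str = "binary") -> MotifMatchMatrix:
    """Scan every ACS with every PSSM and assemble the match matrix.

    ``acs_sequences`` is a list of ``(id, sequence)`` pairs.  All sequences
    are scanned against each motif's exact-null threshold; the matrix entry
    is match presence (binary mode) or match count.
    """
    ids = [i for i, _ in acs_sequences]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ACS ids")
    if mode not in ("binary", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    # Concatenate with single-N separators: any window crossing a boundary
    # contains the N and is penalized out.
    seqs = [s for _, s in acs_sequences]
    joined = "N".join(seqs) if seqs else ""
    codes = encode_sequence(joined)
    starts = np.zeros(len(seqs), dtype=np.int64)
    for k in range(1, len(seqs)):
        starts[k] = starts[k - 1] + len(seqs[k - 1]) + 1
    cols = {}
    for pssm in pssms:
        dist = score_distribution(pssm)
        thr = dist.score_threshold(threshold_p)
        hits = np.zeros(len(seqs), dtype=np.int64)
        for cells in (dist.cell_values, dist.cell_values[::-1, ::-1]):
            win = _window_scores(codes, cells)
            pos = np.flatnonzero(win >= thr - _SCORE_TOL)
            if len(pos):
                seq_idx = np.searchsorted(starts, pos, side="right") - 1
                np.add.at(hits, seq_idx, 1)
        cols[pssm.motif_id] = hits
    N = pd.DataFrame(cols, index=pd.Index(ids, name="acs_id"), dtype=np.int64)
    if mode == "binary":
        N = (N > 0).astype(np.int64)
    return MotifMatchMatrix(N=N, threshold_p=threshold_p, mode=mode)


def matches_to_frame(acs_sequences, pssms, threshold_p: float = 1e-4) -> pd.DataFrame:
    """Per-match table (acs_id, motif_id, offset, strand, score, p_value)."""
    rows = []
    for pssm in pssms:
        dist = score_distribution(pssm)
        for acs_id, seq in acs_sequences:
            for m in scan_sequence(pssm, seq, threshold_p, dist=dist):
                rows.append((acs_id, m.motif_id, m.offset, m.strand, m.score, m.p_value))
    return pd.DataFrame(rows, columns=["acs_id", "motif_id", "offset",
                                       "strand", "score", "p_value"])
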