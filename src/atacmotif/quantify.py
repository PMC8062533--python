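"""Tn5 insertion counting over accessible chromatin sites.

Each ATAC-seq fragment is delimited by two transposase insertion events,
so a fragment interval ``[start, end)`` contributes two insertion points:
its 5' end ``start`` and its 3' end ``end - 1``.  An insertion is counted
for an ACS ``[s, e)`` iff ``s <= point < e``; a fragment can therefore
contribute 0, 1 or 2 counts to an ACS, and overlapping ACS each receive
the insertion.  Fragments are assumed already Tn5-shifted; an optional
flag applies the conventional +4/-5 shift for raw intervals.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import Region

logger = logging.getLogger(__name__)


def insertion_points(fragments: Sequence[Region], shift: bool = False
                     ) -> dict[str, np.ndarray]:
    """Sorted per-chromosome insertion point arrays (two per fragment)."""
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for f in fragments:
        start, end = (f.start + 4, f.end - 5) if shift else (f.start, f.end)
        if end <= start:  # shift can void very short raw fragments
            continue
        by_chrom[f.chrom].append(start)
        by_chrom[f.chrom].append(end - 1)
    return {c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in by_chrom.items()}


def count_insertions(fragments_by_sample: Mapping[str, Sequence[Region]],
                     acs: Sequence[Region], groups: Mapping[str, str] | None = None,
                     shift: bool = False) -> pd.DataFrame:
    """Count insertion events per ACS per sample.

    ``fragments_by_sample`` maps sample id -> fragment Region list.
    Fragments on chromosomes absent from the ACS set are skipped with a
    logged warning.  Returns an integer DataFrame (ACS x samples); group
    labels, when given, are attached as ``DataFrame.attrs['groups']``.
    """
    acs_ids = [r.id for r in acs]
    if len(set(acs_ids)) != len(acs_ids):
        raise ValueError("duplicate ACS ids")
    acs_chroms = {r.chrom for r in acs}
    out = {}
    for sample, frags in fragments_by_sample.items():
        points = insertion_points(frags, shift=shift)
        skipped = sum(len(v) for c, v in points.items() if c not in acs_chroms)
        if skipped:
            logger.warning("sample %s: %d insertion points on chromosomes "
                           "without ACS were skipped", sample, skipped)
        col = np.zeros(len(acs), dtype=np.int64)
        for i, r in enumerate(acs):
            pts = points.get(r.chrom)
            if pts is None:
                continue
            col[i] = np.searchsorted(pts, r.end, side="left") - \
                np.searchsorted(pts, r.start, side="left")
        out[sample] = col
    counts = pd.DataFrame(out, index=pd.Index(acs_ids, name="acs_id"))
    if groups is not None:
        counts.attrs["groups"] = dict(groups)
    return counts


def fragment_size_histogram(fragments: Sequence[Region], bin_width: int = 10
                            ) -> pd.DataFrame:
    """Histogram of fragment sizes (end - start) in left-closed bins.

    Returns a frame with ``bin_start, bin_end, count``; the total count
    equals the number of fragments.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    sizes = np.asarray([f.length for f in fragments], dtype=np.int64)
    if len(sizes) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]).astype(int)
    lo = (sizes.min() // bin_width) * bin_width
    hi = ((sizes.max() // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, _ = np.histogram(sizes, bins=edges)
    return pd.DataFrame({
        "bin_start": edges[:-1], "bin_end": edges[1:], "count": hist,
    })


def plot_fragment_sizes(fragments: Sequence[Region], bin_width: int = 10, ax=None):
    """Fragment-size profile (nucleosome-free and mono-nucleosome modes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h = fragment_size_histogram(fragments, bin_width)
    ax.bar(h["bin_start"], h["count"], width=bin_width, align="edge")
    ax.set_xlabel("fragment size (bp)")
    ax.set_ylabel("fragments")
    return ax
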