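"""Positional meta-analyses.

Three anchored summaries of positions/reads across many transcripts:

* :func:`centile_profile` — each ORF compressed into 100 centiles; per-
  centile site counts normalized to sum 1 (the "metaplot" view that shows
  the 3'-ORF binding bias);
* :func:`anchored_profile` — nucleotide offsets relative to the start codon
  or to the first nucleotide of the stop codon;
* :func:`mode_centered_density` — ribosome-footprint coverage in a window
  around binding-site mode locations, one window per mode, each window
  normalized to its own mean coverage before averaging so deep sites do not
  dominate the aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_targets import TranscriptModel

#: inclusive footprint length ranges per class; 'all' passes everything
CLASS_LENGTH_RANGES = {
    "standard": (28, 30),
    "short": (20, 22),
    "disome": (57, 63),
}


@dataclass
class MetaProfile:
    anchor: str  # start | stop | centile | mode
    bins: np.ndarray
    values: np.ndarray
    n_features: int
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bins, "value": self.values, "n": self.n_features})


def centile_profile(
    positions: Sequence[tuple[str, int]],
    models: Mapping[str, TranscriptModel],
    n_bins: int = 100,
) -> MetaProfile:
    """Site positions mapped to ORF centiles, normalized to unit mass.

    centile = floor(n_bins * (pos - orf_start) / orf_len), clipped to the
    last bin; positions outside their ORF are skipped and counted.
    """
    counts = np.zeros(n_bins, dtype=float)
    used = skipped = 0
    for tid, pos in positions:
        model = models[tid]
        if not model.orf_start <= pos < model.orf_end:
            skipped += 1
            continue
        centile = min(int(n_bins * (pos - model.orf_start) / model.orf_len), n_bins - 1)
        counts[centile] += 1
        used += 1
    total = counts.sum()
    values = counts / total if total > 0 else counts
    return MetaProfile("centile", np.arange(n_bins), values, used, skipped)


def profile_mean_centile(profile: MetaProfile) -> float:
    """Mean centile of a centile profile (bin centers weighted by mass)."""
    if profile.values.sum() == 0:
        return float("nan")
    return float(np.sum(profile.bins * profile.values))


def anchored_profile(
    positions: Sequence[tuple[str, int]],
    models: Mapping[str, TranscriptModel],
    anchor: str,
    window: int,
) -> MetaProfile:
    """Counts of positions at nt offsets in [-window, window] from the anchor.

    anchor='start': offset 0 is the A of the start codon. anchor='stop':
    offset 0 is the first nucleotide of the stop codon. Counts are divided
    by the number of distinct contributing transcripts.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if anchor not in ("start", "stop"):
        raise ValueError(f"unknown anchor {anchor!r}")
    bins = np.arange(-window, window + 1)
    counts = np.zeros(len(bins), dtype=float)
    contributing: set[str] = set()
    for tid, pos in positions:
        model = models[tid]
        ref = model.orf_start if anchor == "start" else model.orf_end - 3
        off = pos - ref
        if -window <= off <= window:
            counts[off + window] += 1
            contributing.add(tid)
    n = len(contributing)
    values = counts / n if n > 0 else counts
    return MetaProfile(anchor, bins, values, n)


def filter_class(reads: pd.DataFrame, footprint_class: str) -> pd.DataFrame:
    """Restrict footprint reads to one length class (exact partition)."""
    if footprint_class == "all":
        return reads
    lo, hi = CLASS_LENGTH_RANGES[footprint_class]
    lengths = reads["end"] - reads["start"]
    return reads[(lengths >= lo) & (lengths <= hi)].reset_index(drop=True)


def mode_centered_density(
    reads: pd.DataFrame,
    modes: Sequence[tuple[str, int]],
    models: Mapping[str, TranscriptModel],
    halfwidth: int = 100,
    per_window_norm: bool = True,
    assignment: str = "center",
) -> MetaProfile:
    """Aggregate footprint density around mode locations.

    ``assignment`` maps each read to positions: "center" (default) puts one
    event at the read midpoint — the point statistic that localizes a
    ribosome relative to the site; "span" adds one to every covered
    nucleotide (coverage-style, flat-topped for long footprints);
    "five_prime" uses the 5' end only. Windows truncated at transcript ends
    contribute only their defined offsets. With ``per_window_norm`` each
    window is divided by its own mean defined value and windows with zero
    mean are excluded. The aggregate is the per-offset mean over windows.
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be > 0")
    if assignment not in ("center", "span", "five_prime"):
        raise ValueError(f"unknown assignment {assignment!r}")
    width = 2 * halfwidth + 1
    bins = np.arange(-halfwidth, halfwidth + 1)
    # per-transcript coverage arrays
    coverage: dict[str, np.ndarray] = {}
    for tid in {tid for tid, _ in modes}:
        coverage[tid] = np.zeros(models[tid].total_len, dtype=float)
    for row in reads.itertuples(index=False):
        cov = coverage.get(row.chrom)
        if cov is None:
            continue
        if assignment == "five_prime":
            pos = row.start if row.strand == "+" else row.end - 1
            if 0 <= pos < len(cov):
                cov[pos] += 1
        elif assignment == "center":
            pos = (row.start + row.end) // 2
            if 0 <= pos < len(cov):
                cov[pos] += 1
        else:
            cov[row.start : row.end] += 1
    total = np.zeros(width, dtype=float)
    n_defined = np.zeros(width, dtype=int)
    n_windows = 0
    excluded = 0
    for tid, mode in modes:
        cov = coverage[tid]
        window = np.full(width, np.nan)
        lo = max(0, mode - halfwidth)
        hi = min(len(cov), mode + halfwidth + 1)
        if hi <= lo:
            excluded += 1
            continue
        window[lo - (mode - halfwidth) : hi - (mode - halfwidth)] = cov[lo:hi]
        defined = ~np.isnan(window)
        if per_window_norm:
            mean = np.nanmean(window)
            if mean == 0:
                excluded += 1
                continue
            window = window / mean
        total[defined] += window[defined]
        n_defined += defined
        n_windows += 1
    values = np.divide(total, n_defined, out=np.zeros(width), where=n_defined > 0)
    return MetaProfile("mode", bins, values, n_windows, excluded)


def profile_peak_offset(profile: MetaProfile) -> int:
    """Offset of the aggregate maximum (leftmost on ties)."""
    return int(profile.bins[int(np.argmax(profile.values))])
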