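"""Motif framing and RNA-structure windows around binding sites.

The binding-site consensus treated here is the degenerate tetramer YGSU
(Y = C/T, S = G/C, U = T on the DNA alphabet). Its diagnostic statistic is
the codon frame of the consensus G: frame = (g_position - orf_start) mod 3.
The ORFome-wide scan of the same pattern is the null against which a framing
bias at binding sites is judged.

Structure propensity comes from per-nucleotide PARS-like tracks (higher =
more structured). PARS30 is the sum over a 30-nt window (about one ribosome
footprint); around a mode location the three windows [-45,-15), [-15,+15)
and [+15,+45) tile [-45,+45) and compare the site to its flanks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate_targets import TranscriptModel

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    match_start: int
    pattern: str
    g_position: int


def _pattern_sets(pattern: str) -> list[set[str]]:
    sets = []
    for symbol in pattern.upper():
        if symbol not in IUPAC:
            raise ValueError(f"non-IUPAC symbol {symbol!r} in pattern")
        sets.append(set(IUPAC[symbol]))
    return sets


def scan_motif(
    sequence: str,
    interval: tuple[int, int] | None = None,
    pattern: str = "YGSU",
    transcript_id: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of an IUPAC pattern in an interval.

    ``g_position`` is match_start + 1, the consensus G of YGSU-like patterns.
    """
    sets = _pattern_sets(pattern)
    start, end = interval if interval is not None else (0, len(sequence))
    if not 0 <= start <= end <= len(sequence):
        raise ValueError(f"interval [{start},{end}) outside sequence of length {len(sequence)}")
    seq = sequence.upper()
    k = len(sets)
    hits = []
    for i in range(start, end - k + 1):
        if all(seq[i + j] in sets[j] for j in range(k)):
            hits.append(MotifHit(transcript_id, i, pattern.upper(), i + 1))
    return hits


def motif_frame(hit: MotifHit, model: TranscriptModel) -> int | None:
    """Codon frame of the consensus G; None when the G is outside the ORF."""
    if not model.orf_start <= hit.g_position < model.orf_end:
        return None
    return (hit.g_position - model.orf_start) % 3


def frame_distribution(
    hits: Sequence[MotifHit],
    models: Mapping[str, TranscriptModel],
    per_site_top: bool = False,
) -> tuple[pd.Series, int]:
    """Proportions of hits per frame {0,1,2}; out-of-ORF hits skipped.

    ``per_site_top`` keeps only the first in-ORF hit per transcript (the
    per-site counting mode); default counts every hit.
    """
    counts = pd.Series(0.0, index=[0, 1, 2])
    skipped = 0
    seen: set[str] = set()
    for hit in hits:
        frame = motif_frame(hit, models[hit.transcript_id])
        if frame is None:
            skipped += 1
            continue
        if per_site_top:
            if hit.transcript_id in seen:
                continue
            seen.add(hit.transcript_id)
        counts[frame] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-ORF motif hits")
    return counts / total, skipped


def orfome_frame_baseline(
    sequences: Mapping[str, str],
    models: Mapping[str, TranscriptModel],
    pattern: str = "YGSU",
) -> pd.Series:
    """Frame distribution of the pattern across every ORF (the null)."""
    hits: list[MotifHit] = []
    for tid, model in models.items():
        seq = sequences[tid]
        hits.extend(scan_motif(seq, (model.orf_start, model.orf_end), pattern, tid))
    proportions, _ = frame_distribution(hits, models)
    return proportions


def edge_frames(
    sites: pd.DataFrame,
    models: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """Frames of each site's leading edge (start) and trailing edge (end-1).

    Returns one row per in-ORF site with its width; out-of-ORF edges are
    dropped. Stratify/aggregate downstream as needed.
    """
    rows = []
    for row in sites.itertuples(index=False):
        model = models.get(row.chrom)
        if model is None:
            continue
        start, end = int(row.start), int(row.end)
        if not (model.orf_start <= start and end <= model.orf_end):
            continue
        rows.append(
            (
                row.chrom,
                start,
                end,
                end - start,
                (start - model.orf_start) % 3,
                (end - 1 - model.orf_start) % 3,
            )
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "start", "end", "width", "leading_frame", "trailing_frame"]
    )


def edge_frame_distributions(edges: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    lead = edges["leading_frame"].value_counts(normalize=True).reindex([0, 1, 2], fill_value=0.0)
    trail = edges["trailing_frame"].value_counts(normalize=True).reindex([0, 1, 2], fill_value=0.0)
    return lead, trail


def track_array(track: pd.DataFrame, transcript_id: str, total_len: int) -> np.ndarray:
    """Dense per-nt score array (NaN where undefined) for one transcript."""
    arr = np.full(total_len, np.nan)
    sub = track[track["transcript_id"] == transcript_id]
    arr[sub["pos"].to_numpy()] = sub["score"].to_numpy()
    return arr


def pars_mean(track: np.ndarray, interval: tuple[int, int]) -> float:
    """Mean score over defined positions of the interval; NaN if none."""
    lo, hi = interval
    lo, hi = max(lo, 0), min(hi, len(track))
    if hi <= lo:
        return float("nan")
    window = track[lo:hi]
    if np.isnan(window).all():
        return float("nan")
    return float(np.nanmean(window))


def pars30(track: np.ndarray, window_start: int, window_len: int = 30) -> float:
    """Sum of scores over [window_start, window_start+window_len).

    NaN (flagged) when the window leaves the track or touches any undefined
    position — a partial footprint window is not comparable to a full one.
    """
    lo, hi = window_start, window_start + window_len
    if lo < 0 or hi > len(track):
        return float("nan")
    window = track[lo:hi]
    if np.isnan(window).any():
        return float("nan")
    return float(window.sum())


#: mode-relative half-open windows tiling [-45, +45)
PARS30_WINDOWS = {"upstream": (-45, -15), "site": (-15, 15), "downstream": (15, 45)}


def pars30_around_mode(track: np.ndarray, mode: int) -> dict[str, float]:
    """PARS30 sums upstream of, at, and downstream of a mode location."""
    spans = sorted(PARS30_WINDOWS.values())
    for (_, a_end), (b_start, _) in zip(spans, spans[1:]):
        assert a_end == b_start, "windows must tile without gap/overlap"
    return {
        name: pars30(track, mode + rel_start, rel_end - rel_start)
        for name, (rel_start, rel_end) in PARS30_WINDOWS.items()
    }


def pars30_site_table(
    track: pd.DataFrame,
    modes: Sequence[tuple[str, int]],
    models: Mapping[str, TranscriptModel],
) -> pd.DataFrame:
    """pars30_around_mode for many sites, as a table (NaNs = flagged)."""
    arrays = {
        tid: track_array(track, tid, models[tid].total_len) for tid in {t for t, _ in modes}
    }
    rows = []
    for tid, mode in modes:
        sums = pars30_around_mode(arrays[tid], mode)
        rows.append((tid, mode, sums["upstream"], sums["site"], sums["downstream"]))
    return pd.DataFrame(rows, columns=["transcript_id", "mode", "upstream", "site", "downstream"])
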