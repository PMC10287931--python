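"""Assign called sites to transcript regions and define target RNA sets.

A transcript is modelled as 5'UTR + ORF + 3'UTR tiling [0, total_len).
A site is labelled by the region containing its mode location (the site's
point summary), so boundary-spanning sites follow the mode. Transcripts with
at least one accepted site are targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

REGIONS = ("5UTR", "ORF", "3UTR", "ncRNA", "intergenic")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's segment bounds (0-based half-open, transcript space)."""

    transcript_id: str
    total_len: int
    utr5_len: int
    orf_start: int
    orf_end: int
    biotype: str = "mRNA"

    def __post_init__(self):
        if not (0 <= self.utr5_len == self.orf_start <= self.orf_end <= self.total_len):
            raise ValueError(f"{self.transcript_id}: segments do not tile [0,{self.total_len})")
        if self.biotype == "mRNA" and (self.orf_end - self.orf_start) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: mRNA ORF length not divisible by 3")

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start


def models_from_annotation(annotation: pd.DataFrame) -> dict[str, TranscriptModel]:
    return {
        row.transcript_id: TranscriptModel(
            transcript_id=row.transcript_id,
            total_len=int(row.total_len),
            utr5_len=int(row.utr5_len),
            orf_start=int(row.orf_start),
            orf_end=int(row.orf_end),
            biotype=getattr(row, "biotype", "mRNA"),
        )
        for row in annotation.itertuples(index=False)
    }


def assign_region(mode_location: int, model: TranscriptModel) -> str:
    """Region label of the position; non-mRNA transcripts are 'ncRNA'."""
    if not 0 <= mode_location < model.total_len:
        raise ValueError(
            f"mode {mode_location} outside transcript {model.transcript_id} "
            f"[0,{model.total_len})"
        )
    if model.biotype != "mRNA":
        return "ncRNA"
    if mode_location < model.orf_start:
        return "5UTR"
    if mode_location < model.orf_end:
        return "ORF"
    return "3UTR"


def annotate_sites(sites: pd.DataFrame, models: Mapping[str, TranscriptModel]) -> pd.DataFrame:
    """Add a region_label column (sites on unknown transcripts -> intergenic)."""
    labels = []
    for row in sites.itertuples(index=False):
        model = models.get(row.chrom)
        if model is None:
            labels.append("intergenic")
        else:
            labels.append(assign_region(int(row.mode_location), model))
    out = sites.copy()
    out["region_label"] = labels
    return out


def define_targets(sites: pd.DataFrame) -> set[str]:
    """Transcripts with at least one accepted binding site."""
    return set(sites["chrom"].unique()) if len(sites) else set()


def region_distribution(sites: pd.DataFrame) -> pd.Series:
    """Proportion of sites per region label (sums to 1)."""
    if "region_label" not in sites.columns:
        raise ValueError("sites must be annotated first (annotate_sites)")
    counts = sites["region_label"].value_counts()
    return (counts / counts.sum()).reindex(counts.index)


def sites_per_target(sites: pd.DataFrame) -> pd.Series:
    """Histogram: number of targets having k sites, indexed by k."""
    per = sites.groupby("chrom").size()
    return per.value_counts().sort_index()


def overlap_sets(named_sets: Mapping[str, set]) -> dict[str, int]:
    """Venn-style exclusive segment counts for 2+ named sets.

    Keys are '&'-joined sorted member names; each element is counted in the
    segment of exactly the sets containing it.
    """
    names = sorted(named_sets)
    universe = set().union(*named_sets.values()) if named_sets else set()
    segments: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set(universe)
            for name in combo:
                inside &= named_sets[name]
            for name in names:
                if name not in combo:
                    inside -= named_sets[name]
            segments["&".join(combo)] = len(inside)
    return segments


def quintile_distribution(
    targets: set[str],
    score_table: pd.DataFrame,
    score_column: str = "score",
    n_bins: int = 5,
) -> tuple[pd.Series, int]:
    """Distribution of targets across score quintiles of an external table.

    Transcripts are ranked (stable ties) into ``n_bins`` equal-count bins;
    bin ``n_bins`` holds the highest scores. Returns (proportions indexed
    1..n_bins summing to 1, number of unscored targets).
    """
    scored = score_table.dropna(subset=[score_column]).copy()
    order = scored[score_column].rank(method="first")
    scored["quintile"] = (np.ceil(order / len(scored) * n_bins)).astype(int).clip(1, n_bins)
    lookup = scored.set_index("transcript_id")["quintile"]
    in_bins = pd.Series(0, index=range(1, n_bins + 1), dtype=float)
    unscored = 0
    for tid in targets:
        if tid in lookup.index:
            in_bins[int(lookup[tid])] += 1
        else:
            unscored += 1
    total = in_bins.sum()
    if total > 0:
        in_bins = in_bins / total
    return in_bins, unscored
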