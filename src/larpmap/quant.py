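"""Per-transcript quantification and rank statistics.

rpkm here means reads per million library reads per kilobase of coding
sequence: ``(count / library_total * 1e6) / cds_len_kb``. Derived ratios:

* CLIP enrichment  = CLIP rpkm / total-RNA rpkm
* translation efficiency (TE) = footprint rpkm / RNA rpkm
* disome abundance = disome-footprint rpkm / RNA rpkm (TE-equivalent for
  collided-ribosome footprints)

Denominator transcripts below a small RNA-rpkm floor are excluded with a
reason code rather than producing unstable ratios. The polysome:monosome
contract is a median-of-ratios size-factor-normalized log2 ratio with a
pseudocount — a deliberate simplification of a full negative-binomial
differential model, and labelled as such.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

RNA_RPKM_FLOOR = 0.1


def rpkm(count: float, library_total: float, cds_len_kb: float) -> float:
    """Reads per million per kb; NaN when a denominator is unusable."""
    if library_total <= 0 or cds_len_kb <= 0:
        return float("nan")
    return (count / library_total * 1e6) / cds_len_kb


def rpkm_column(counts: pd.Series, cds_len_kb: pd.Series) -> pd.Series:
    """Vectorized rpkm with the library total taken from the column sum."""
    total = counts.sum()
    if total <= 0:
        return pd.Series(np.nan, index=counts.index)
    out = (counts / total * 1e6) / cds_len_kb
    return out.where(cds_len_kb > 0)


def _ratio(numer: float, denom: float, floor: float) -> tuple[float, str]:
    if not (denom == denom) or denom < floor:  # NaN or below floor
        return float("nan"), "low_rna"
    return numer / denom, "ok"


def clip_enrichment(clip_rpkm: float, rna_rpkm: float, floor: float = RNA_RPKM_FLOOR) -> float:
    """CLIP rpkm over RNA rpkm; NaN (excluded) below the RNA floor."""
    value, _ = _ratio(clip_rpkm, rna_rpkm, floor)
    return value


def translation_efficiency(rpf_rpkm: float, rna_rpkm: float, floor: float = RNA_RPKM_FLOOR) -> float:
    value, _ = _ratio(rpf_rpkm, rna_rpkm, floor)
    return value


def disome_abundance(disome_rpkm: float, rna_rpkm: float, floor: float = RNA_RPKM_FLOOR) -> float:
    value, _ = _ratio(disome_rpkm, rna_rpkm, floor)
    return value


def count_reads_per_transcript(reads: pd.DataFrame) -> pd.Series:
    """Reads per transcript (chrom column), as a Series."""
    if len(reads) == 0:
        return pd.Series(dtype=int)
    return reads.groupby("chrom").size()


def clip_reads_in_clusters(reads: pd.DataFrame, sites: pd.DataFrame) -> pd.Series:
    """Per-transcript count of CLIP reads overlapping an accepted site.

    Only reads inside accepted clusters count toward CLIP rpkm.
    """
    counts: dict[str, int] = {}
    site_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in sites.itertuples(index=False):
        site_by_chrom.setdefault(row.chrom, []).append((int(row.start), int(row.end)))
    for row in reads.itertuples(index=False):
        for s, e in site_by_chrom.get(row.chrom, ()):
            if row.start < e and row.end > s:
                counts[row.chrom] = counts.get(row.chrom, 0) + 1
                break
    return pd.Series(counts, dtype=int)


def build_expression_table(
    annotation: pd.DataFrame,
    clip_counts: pd.Series | None = None,
    rna_counts: pd.Series | None = None,
    rpf_standard_counts: pd.Series | None = None,
    rpf_short_counts: pd.Series | None = None,
    disome_counts: pd.Series | None = None,
    rna_floor: float = RNA_RPKM_FLOOR,
) -> pd.DataFrame:
    """Assemble counts, rpkm columns and derived ratios per transcript."""
    table = annotation[["transcript_id"]].copy()
    table["cds_len_kb"] = (annotation["orf_end"] - annotation["orf_start"]) / 1000.0
    table = table.set_index("transcript_id")
    assays = {
        "clip": clip_counts,
        "rna": rna_counts,
        "rpf_standard": rpf_standard_counts,
        "rpf_short": rpf_short_counts,
        "disome": disome_counts,
    }
    for assay, counts in assays.items():
        if counts is None:
            continue
        col = counts.reindex(table.index).fillna(0).astype(float)
        table[f"{assay}_reads"] = col
        table[f"{assay}_rpkm"] = rpkm_column(col, table["cds_len_kb"])
    if "clip_rpkm" in table and "rna_rpkm" in table:
        table["clip_enrichment"] = table["clip_rpkm"] / table["rna_rpkm"].where(
            table["rna_rpkm"] >= rna_floor
        )
    if "rpf_standard_rpkm" in table and "rna_rpkm" in table:
        table["te_standard"] = table["rpf_standard_rpkm"] / table["rna_rpkm"].where(
            table["rna_rpkm"] >= rna_floor
        )
    if "disome_rpkm" in table and "rna_rpkm" in table:
        table["disome_abundance"] = table["disome_rpkm"] / table["rna_rpkm"].where(
            table["rna_rpkm"] >= rna_floor
        )
    return table.reset_index()


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (columns = libraries, rows = transcripts)."""
    logs = np.log(counts.where(counts > 0))
    # geometric mean defined only for transcripts positive in every library
    log_geomean = logs.mean(axis=1, skipna=False)
    usable = log_geomean.notna()
    if not usable.any():
        raise ValueError("no transcript observed in every library")
    factors = {}
    for col in counts.columns:
        ratios = np.log(counts.loc[usable, col]) - log_geomean[usable]
        factors[col] = float(np.exp(np.median(ratios.dropna())))
    return pd.Series(factors)


def poly_mono_ratio(
    poly_counts: pd.Series,
    mono_counts: pd.Series,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-transcript log2 polysome:monosome ratio after size-factor
    normalization. Pseudocount keeps zero-count transcripts finite."""
    if poly_counts.sum() == 0 or mono_counts.sum() == 0:
        raise ValueError("all-zero library")
    counts = pd.DataFrame({"poly": poly_counts, "mono": mono_counts}).fillna(0.0)
    sf = size_factors(counts)
    norm_p = counts["poly"] / sf["poly"] + pseudocount
    norm_m = counts["mono"] / sf["mono"] + pseudocount
    return np.log2(norm_p / norm_m)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for sample a (ties count 1/2)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def rank_compare(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney rank test: exact enumeration for nA+nB <= 12, else the
    normal approximation with tie correction.

    Exact two-sided p: the probability, over all C(n, nA) label assignments
    of the pooled values, of a U at least as far from nA*nB/2 as observed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty group")
    u_obs = _u_statistic(a, b)
    n_a, n_b = len(a), len(b)
    if n_a + n_b <= 12:
        pooled = np.concatenate([a, b])
        center = n_a * n_b / 2.0
        dev = abs(u_obs - center)
        hits = total = 0
        for combo in combinations(range(len(pooled)), n_a):
            mask = np.zeros(len(pooled), dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev - 1e-12:
                hits += 1
        return u_obs, hits / total
    result = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(result.statistic), float(result.pvalue)
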