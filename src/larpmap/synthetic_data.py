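"""Synthetic data with known ground truth.

This module emulates the data regime of a yeast LARP (La-related protein)
PAR-CLIP / ribosome-profiling study on a toy transcriptome:

* transcripts with 5'UTR + ORF + 3'UTR, ORFs starting ATG and ending a stop;
* planted protein-RNA crosslink sites inside ORFs with a tunable bias toward
  the ORF 3' end (density proportional to ((pos - orf_start)/orf_len)**bias);
* optionally a YGSU motif written into the sequence at each site with its G
  at a controlled codon frame;
* CLIP reads of 13-40 nt covering the crosslink, each carrying a T->C
  conversion at the crosslink with a stated probability, plus uniform
  background reads that never carry conversions;
* ribosome-footprint reads in three length classes — standard (28-30 nt),
  short (20-22 nt) and disome (57-63 nt) — centered at a stated offset from
  the planted site;
* RNA-seq counts from stated abundances, per-nucleotide structure tracks
  elevated at planted sites, and zero-/low-noise reporter and qPCR tables.

Everything is driven by a single integer seed: identical configuration gives
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import BED6_COLUMNS, READ_COLUMNS

STOP_CODONS = ("TAA", "TAG", "TGA")

#: footprint length ranges, inclusive
FOOTPRINT_CLASSES = {
    "standard": (28, 30),
    "short": (20, 22),
    "disome": (57, 63),
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults are the regime the analyses are exercised in: 20 transcripts,
    20 crosslink sites skewed to ORF 3' ends (bias exponent 3), CLIP reads of
    13-40 nt at 50x expected depth per site with a 0.5 conversion rate and
    10% background reads, and footprint classes centered on the site (offset
    0) except disomes at +30 nt (the leading, stalled ribosome ahead of the
    crosslinked protein).
    """

    n_transcripts: int = 20
    n_sites: int = 20
    orf_length_range: tuple[int, int] = (300, 900)
    utr5_length_range: tuple[int, int] = (20, 60)
    utr3_length_range: tuple[int, int] = (50, 150)
    site_positional_bias: float = 3.0
    motif_insertion_frame: int | None = None
    conversion_rate: float = 0.5
    read_length_range: tuple[int, int] = (13, 40)
    depth_per_site: float = 50.0
    background_read_fraction: float = 0.10
    footprint_offsets: Mapping[str, int] = field(
        default_factory=lambda: {"standard": 0, "short": 0, "disome": 30}
    )
    footprint_jitter_sd: float = 2.0
    footprint_depth_per_site: float = 100.0
    footprint_background_fraction: float = 0.10
    rna_abundance_dispersion: float = 0.1
    min_site_separation: int = 120
    seed: int = 0

    def validate(self) -> None:
        for name in ("orf_length_range", "utr5_length_range", "utr3_length_range", "read_length_range"):
            lo, hi = getattr(self, name)
            if hi < lo or lo < 0:
                raise ConfigError(f"{name}: degenerate range ({lo},{hi})")
        if self.orf_length_range[0] < 9:
            raise ConfigError("orf_length_range: ORF must hold start + >=1 codon + stop")
        if not 0.0 <= self.conversion_rate <= 1.0:
            raise ConfigError(f"conversion_rate {self.conversion_rate} outside [0,1]")
        if self.site_positional_bias < 0:
            raise ConfigError(f"site_positional_bias {self.site_positional_bias} < 0")
        if self.motif_insertion_frame is not None and self.motif_insertion_frame not in (0, 1, 2):
            raise ConfigError(f"motif_insertion_frame {self.motif_insertion_frame} not in {{0,1,2}}")
        if self.n_transcripts < 0 or self.n_sites < 0:
            raise ConfigError("counts must be >= 0")
        if self.depth_per_site < 0 or self.footprint_depth_per_site < 0:
            raise ConfigError("depths must be >= 0")
        for cls in self.footprint_offsets:
            if cls not in FOOTPRINT_CLASSES:
                raise ConfigError(f"unknown footprint class {cls!r}")


@dataclass(frozen=True)
class SiteTruth:
    """Ground truth for one planted crosslink site."""

    transcript_id: str
    crosslink_pos: int
    motif_present: bool
    motif_frame: int | None
    planted_footprint_classes: frozenset[str] = frozenset({"standard", "short", "disome"})


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


def _random_codon(rng: np.random.Generator) -> str:
    bases = "ACGT"
    while True:
        codon = "".join(rng.choice(list(bases), size=3))
        if codon not in STOP_CODONS and codon != "ATG":
            return codon


def generate_transcriptome(cfg: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate sequences and the matching annotation table.

    Each transcript is 5'UTR + ORF + 3'UTR; the ORF starts with ATG, ends
    with a stop codon, contains no internal stop in frame 0, and its length
    is rounded to a multiple of 3 inside the configured range.
    """
    cfg.validate()
    rng = _rng(cfg)
    sequences: dict[str, str] = {}
    rows = []
    for i in range(cfg.n_transcripts):
        tid = f"t{i + 1:04d}"
        u5 = int(rng.integers(cfg.utr5_length_range[0], cfg.utr5_length_range[1] + 1))
        u3 = int(rng.integers(cfg.utr3_length_range[0], cfg.utr3_length_range[1] + 1))
        orf_len = int(rng.integers(cfg.orf_length_range[0], cfg.orf_length_range[1] + 1))
        orf_len -= orf_len % 3
        orf_len = max(orf_len, 9)
        n_internal = orf_len // 3 - 2
        orf = "ATG" + "".join(_random_codon(rng) for _ in range(n_internal))
        orf += str(rng.choice(STOP_CODONS))
        utr5 = "".join(rng.choice(list("ACGT"), size=u5))
        utr3 = "".join(rng.choice(list("ACGT"), size=u3))
        seq = utr5 + orf + utr3
        sequences[tid] = seq
        rows.append((tid, u5, u5, u5 + orf_len, len(seq)))
    annotation = pd.DataFrame(
        rows, columns=["transcript_id", "utr5_len", "orf_start", "orf_end", "total_len"]
    )
    annotation["biotype"] = "mRNA"
    return sequences, annotation


def _sample_orf_position(rng, orf_start: int, orf_len: int, bias: float) -> int:
    # density proportional to x**bias on (0,1]: inverse-CDF sample u**(1/(bias+1))
    x = rng.random() ** (1.0 / (bias + 1.0))
    pos = orf_start + min(int(x * orf_len), orf_len - 1)
    return pos


def _iupac_choice(rng, symbol: str) -> str:
    options = {"Y": "CT", "S": "GC"}[symbol]
    return options[int(rng.integers(len(options)))]


def plant_sites(
    annotation: pd.DataFrame,
    sequences: Mapping[str, str],
    cfg: SimConfig,
) -> tuple[list[SiteTruth], dict[str, str]]:
    """Plant crosslink sites into ORFs; returns truth and edited sequences.

    Sites are drawn with density proportional to
    ``((pos - orf_start)/orf_len)**site_positional_bias`` so bias 0 is
    uniform and larger values skew toward the stop codon. When
    ``motif_insertion_frame`` is set, a concrete YGSU instance (Y in {C,T},
    S in {G,C}, U=T on the DNA alphabet) is written into the sequence with
    its G at that codon frame and the crosslink placed on the motif U (a T,
    the photoreactive base). Without a motif the crosslink base is forced
    to T.
    """
    cfg.validate()
    if len(annotation) == 0:
        raise ConfigError("plant_sites: empty annotation")
    rng = _rng(cfg.seed + 1)
    seqs = {tid: list(s) for tid, s in sequences.items()}
    ann = annotation.set_index("transcript_id")
    tids = list(ann.index)
    truth: list[SiteTruth] = []
    taken: dict[str, list[int]] = {tid: [] for tid in tids}
    for _ in range(cfg.n_sites):
        tid = tids[int(rng.integers(len(tids)))]
        row = ann.loc[tid]
        orf_start, orf_end = int(row.orf_start), int(row.orf_end)
        orf_len = orf_end - orf_start
        for _attempt in range(200):
            pos = _sample_orf_position(rng, orf_start, orf_len, cfg.site_positional_bias)
            # keep planted sites separable (min_site_separation nt apart),
            # clear of the start codon and with motif room before the stop
            if pos < orf_start + 7 or pos > orf_end - 5:
                continue
            if all(abs(pos - p) >= cfg.min_site_separation for p in taken[tid]):
                break
        else:
            continue
        taken[tid].append(pos)
        if cfg.motif_insertion_frame is not None:
            frame = cfg.motif_insertion_frame
            # place the motif G at the configured frame; crosslink on its U
            g_pos = pos - 2
            g_pos -= (g_pos - orf_start - frame) % 3
            motif = _iupac_choice(rng, "Y") + "G" + _iupac_choice(rng, "S") + "T"
            for k, base in enumerate(motif):
                seqs[tid][g_pos - 1 + k] = base
            crosslink = g_pos + 2
            truth.append(SiteTruth(tid, crosslink, True, frame))
        else:
            seqs[tid][pos] = "T"
            truth.append(SiteTruth(tid, pos, False, None))
    truth.sort(key=lambda s: (s.transcript_id, s.crosslink_pos))
    return truth, {tid: "".join(s) for tid, s in seqs.items()}


def truth_table(truth: Sequence[SiteTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                s.transcript_id,
                s.crosslink_pos,
                s.motif_present,
                -1 if s.motif_frame is None else s.motif_frame,
                ",".join(sorted(s.planted_footprint_classes)),
            )
            for s in truth
        ],
        columns=["transcript_id", "crosslink_pos", "motif_present", "motif_frame", "footprint_classes"],
    )


def simulate_parclip_reads(
    truth: Sequence[SiteTruth],
    annotation: pd.DataFrame,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Simulate CLIP reads as a conversion-read table.

    Per site the read count is Poisson(depth_per_site); lengths are uniform
    in ``read_length_range``; each read covers the crosslink and carries a
    conversion there with probability ``conversion_rate``. Background reads
    (a ``background_read_fraction`` fraction of the expected site reads) are
    scattered uniformly along transcripts and never carry conversions.
    """
    cfg.validate()
    rng = _rng(cfg.seed + 2)
    ann = annotation.set_index("transcript_id")
    lo, hi = cfg.read_length_range
    rows = []
    n_site_reads = 0
    for site in truth:
        total_len = int(ann.loc[site.transcript_id].total_len)
        n_reads = int(rng.poisson(cfg.depth_per_site))
        n_site_reads += n_reads
        for j in range(n_reads):
            length = int(rng.integers(lo, hi + 1))
            start_min = max(0, site.crosslink_pos - length + 1)
            start_max = min(site.crosslink_pos, total_len - length)
            if start_max < start_min:
                continue
            start = int(rng.integers(start_min, start_max + 1))
            offset = site.crosslink_pos - start
            converted = rng.random() < cfg.conversion_rate
            rows.append(
                (
                    site.transcript_id,
                    start,
                    start + length,
                    f"site_{site.transcript_id}_{site.crosslink_pos}_{j}",
                    "0",
                    "+",
                    (offset,) if converted else (),
                )
            )
    expected_site_reads = cfg.depth_per_site * len(truth)
    n_background = int(rng.poisson(cfg.background_read_fraction * expected_site_reads))
    tids = list(ann.index)
    for j in range(n_background):
        tid = tids[int(rng.integers(len(tids)))]
        total_len = int(ann.loc[tid].total_len)
        length = int(rng.integers(lo, hi + 1))
        if total_len <= length:
            continue
        start = int(rng.integers(0, total_len - length + 1))
        rows.append((tid, start, start + length, f"bg_{j}", "0", "+", ()))
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return reads.sort_values(["chrom", "start", "end", "name"], kind="stable").reset_index(drop=True)


def simulate_footprints(
    truth: Sequence[SiteTruth],
    annotation: pd.DataFrame,
    cfg: SimConfig,
    footprint_class: str,
) -> pd.DataFrame:
    """Simulate footprint reads (BED6) for one length class.

    Read centers fall at ``crosslink_pos + footprint_offsets[class]`` plus
    Gaussian jitter (sd ``footprint_jitter_sd``, rounded to int); lengths
    are uniform in the class range. Background reads are uniform along ORFs.
    """
    cfg.validate()
    if footprint_class not in FOOTPRINT_CLASSES:
        raise ConfigError(f"unknown footprint class {footprint_class!r}")
    lo, hi = FOOTPRINT_CLASSES[footprint_class]
    offset = int(cfg.footprint_offsets.get(footprint_class, 0))
    # class index keeps the per-class streams independent
    cls_idx = sorted(FOOTPRINT_CLASSES).index(footprint_class)
    rng = _rng(cfg.seed + 10 + cls_idx)
    ann = annotation.set_index("transcript_id")
    rows = []
    for site in truth:
        if footprint_class not in site.planted_footprint_classes:
            continue
        total_len = int(ann.loc[site.transcript_id].total_len)
        n_reads = int(rng.poisson(cfg.footprint_depth_per_site))
        for j in range(n_reads):
            length = int(rng.integers(lo, hi + 1))
            jitter = int(round(rng.normal(0.0, cfg.footprint_jitter_sd))) if cfg.footprint_jitter_sd > 0 else 0
            center = site.crosslink_pos + offset + jitter
            start = center - length // 2
            start = max(0, min(start, total_len - length))
            if start < 0:
                continue
            rows.append(
                (site.transcript_id, start, start + length,
                 f"fp_{footprint_class}_{site.transcript_id}_{site.crosslink_pos}_{j}", "0", "+")
            )
    expected = cfg.footprint_depth_per_site * len(truth)
    n_background = int(rng.poisson(cfg.footprint_background_fraction * expected))
    tids = list(ann.index)
    for j in range(n_background):
        tid = tids[int(rng.integers(len(tids)))]
        row = ann.loc[tid]
        length = int(rng.integers(lo, hi + 1))
        lo_start, hi_start = int(row.orf_start), int(row.orf_end) - length
        if hi_start <= lo_start:
            continue
        start = int(rng.integers(lo_start, hi_start + 1))
        rows.append((tid, start, start + length, f"fp_{footprint_class}_bg_{j}", "0", "+"))
    reads = pd.DataFrame(rows, columns=BED6_COLUMNS)
    return reads.sort_values(["chrom", "start", "end", "name"], kind="stable").reset_index(drop=True)


def simulate_background_footprints(
    annotation: pd.DataFrame,
    cfg: SimConfig,
    footprint_class: str,
    n_reads: int,
) -> pd.DataFrame:
    """Uniform ORF background only — the null for flatness checks."""
    if footprint_class not in FOOTPRINT_CLASSES:
        raise ConfigError(f"unknown footprint class {footprint_class!r}")
    lo, hi = FOOTPRINT_CLASSES[footprint_class]
    rng = _rng(cfg.seed + 20)
    ann = annotation.set_index("transcript_id")
    tids = list(ann.index)
    rows = []
    for j in range(n_reads):
        tid = tids[int(rng.integers(len(tids)))]
        row = ann.loc[tid]
        length = int(rng.integers(lo, hi + 1))
        lo_start, hi_start = int(row.orf_start), int(row.orf_end) - length
        if hi_start <= lo_start:
            continue
        start = int(rng.integers(lo_start, hi_start + 1))
        rows.append((tid, start, start + length, f"bg_{j}", "0", "+"))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def simulate_rnaseq(
    annotation: pd.DataFrame,
    abundances: Mapping[str, float] | pd.Series,
    seed: int,
    dispersion: float = 0.0,
) -> pd.DataFrame:
    """RNA-seq counts per transcript: Poisson, or gamma-Poisson if dispersed.

    ``abundances`` are expected read counts. ``dispersion`` is the squared
    coefficient of variation of the gamma mixing distribution (0 = Poisson).
    """
    rng = np.random.default_rng(seed)
    abundances = pd.Series(abundances)
    if (abundances < 0).any():
        raise ConfigError("negative abundance")
    rows = []
    for tid in annotation.transcript_id:
        mu = float(abundances.get(tid, 0.0))
        if dispersion > 0 and mu > 0:
            shape = 1.0 / dispersion
            mu = rng.gamma(shape, mu / shape)
        rows.append((tid, int(rng.poisson(mu))))
    return pd.DataFrame(rows, columns=["transcript_id", "count"])


def simulate_pars_track(
    annotation: pd.DataFrame,
    truth: Sequence[SiteTruth],
    baseline: float,
    site_boost: float,
    seed: int,
    noise_sd: float = 0.0,
    boost_halfwidth: int = 15,
) -> pd.DataFrame:
    """Per-nucleotide structure-score track, elevated around planted sites.

    Scores are ``baseline`` everywhere plus ``site_boost`` within
    ``boost_halfwidth`` nt of each crosslink, plus optional Gaussian noise.
    """
    if baseline < 0 or site_boost < 0:
        raise ConfigError("negative baseline/boost")
    rng = np.random.default_rng(seed)
    site_pos: dict[str, list[int]] = {}
    for s in truth:
        site_pos.setdefault(s.transcript_id, []).append(s.crosslink_pos)
    frames = []
    for row in annotation.itertuples(index=False):
        n = int(row.total_len)
        score = np.full(n, baseline, dtype=float)
        for pos in site_pos.get(row.transcript_id, []):
            lo = max(0, pos - boost_halfwidth)
            hi = min(n, pos + boost_halfwidth + 1)
            score[lo:hi] += site_boost
        if noise_sd > 0:
            score = score + rng.normal(0.0, noise_sd, size=n)
        frames.append(
            pd.DataFrame(
                {"transcript_id": row.transcript_id, "pos": np.arange(n), "score": score}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_reporter_table(
    true_rates: Mapping[str, float],
    noise_cv: float,
    seed: int,
    n_replicates: int = 3,
    control_reporter: str = "CAA",
    control_ratio: float = 0.5,
    rluc: float = 1_000_000.0,
) -> pd.DataFrame:
    """Dual-luciferase luminometer table from known readthrough/frameshift %.

    ``true_rates`` maps reporter name -> true percentage relative to the
    control reporter (which itself is included at 100%). With ``noise_cv``
    0 the quantification operations invert the table exactly.
    """
    for name, rate in true_rates.items():
        if rate < 0:
            raise ConfigError(f"negative rate for {name}")
    rng = np.random.default_rng(seed)
    rows = []
    reporters = {control_reporter: 100.0, **dict(true_rates)}
    for rep in range(1, n_replicates + 1):
        for reporter, pct in reporters.items():
            ratio = control_ratio * pct / 100.0
            fluc = ratio * rluc
            if noise_cv > 0:
                fluc *= max(0.0, 1.0 + rng.normal(0.0, noise_cv))
            rows.append(("sim", "sim", reporter, fluc, rluc, rep))
    return pd.DataFrame(
        rows, columns=["strain", "condition", "reporter", "fluc", "rluc", "replicate"]
    )


def simulate_qpcr_table(
    true_fractions: Mapping[str, Sequence[float]],
    efficiencies: Mapping[str, float],
    seed: int,
    noise_sd: float = 0.0,
    spike_cq: float = 20.0,
    cq_scale: float = 30.0,
) -> pd.DataFrame:
    """qPCR Cq table from known per-fraction RNA amounts.

    ``true_fractions``: gene -> relative amount per fraction.  Cq values are
    ``cq_scale - log_E(amount)``; the spike-in is constant across fractions,
    so the efficiency-corrected delta-delta-Ct quantification recovers the
    amounts exactly at ``noise_sd`` 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene, amounts in true_fractions.items():
        eff = float(efficiencies[gene])
        if eff <= 1.0:
            raise ConfigError(f"amplification factor for {gene} must exceed 1")
        for i, amount in enumerate(amounts, start=1):
            if amount < 0:
                raise ConfigError("negative amount")
            if amount == 0:
                cq = float("nan")
            else:
                cq = cq_scale - math.log(amount, eff)
                if noise_sd > 0:
                    cq += rng.normal(0.0, noise_sd)
            rows.append((gene, f"F{i}", cq, spike_cq, eff, float(efficiencies.get("spike", 2.0))))
    return pd.DataFrame(
        rows,
        columns=["target", "fraction", "cq", "spike_cq", "efficiency", "spike_efficiency"],
    )


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    return replace(cfg, seed=seed)
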