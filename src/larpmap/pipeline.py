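"""End-to-end orchestration of the synthetic demo / analysis pipeline.

Stages run in dependency order: simulate -> call-sites -> annotate -> quant
-> metagene -> framing -> structure -> reporters -> qpcr. Every run writes a
provenance JSON carrying the full configuration, its hash, and per-stage
record counts; identical configuration reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate_targets, formats_io, framing_structure, metagene, quant, reporter_quant
from .site_calling import SiteCallParams, call_sites_from_reads
from .synthetic_data import (
    FOOTPRINT_CLASSES,
    SimConfig,
    simulate_footprints,
    simulate_parclip_reads,
    simulate_pars_track,
    simulate_qpcr_table,
    simulate_reporter_table,
    simulate_rnaseq,
    generate_transcriptome,
    plant_sites,
    truth_table,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the stated thresholds."""

    seed: int = 1
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    call: SiteCallParams = field(default_factory=SiteCallParams)
    halfwidth: int = 100
    motif_pattern: str = "YGSU"
    rna_floor: float = quant.RNA_RPKM_FLOOR
    pseudocount: float = 0.5
    pars_baseline: float = 0.5
    pars_site_boost: float = 2.0
    true_readthrough: dict = field(
        default_factory=lambda: {"UAA": 1.0, "UAG": 2.0, "UGA": 5.0}
    )
    true_frameshift: dict = field(
        default_factory=lambda: {"fs_minus1": 5.0, "fs_plus1": 8.0}
    )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["footprint_offsets"] = dict(d["sim"]["footprint_offsets"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sim = data.pop("sim", {})
        call = data.pop("call", {})
        cfg = cls(**data)
        if sim:
            if "orf_length_range" in sim:
                sim = {
                    k: tuple(v) if k.endswith("_range") else v for k, v in sim.items()
                }
            cfg.sim = SimConfig(**sim)
        if call:
            cfg.call = SiteCallParams(**call)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage into ``outdir``; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    if not config.simulate:
        raise NotImplementedError(
            "external-input runs use the per-stage subcommands; the pipeline "
            "driver currently orchestrates the synthetic demo"
        )

    sim = dataclasses.replace(config.sim, seed=config.seed)

    # --- simulate ---------------------------------------------------------
    sequences, annotation = generate_transcriptome(sim)
    truth, sequences = plant_sites(annotation, sequences, sim)
    reads = simulate_parclip_reads(truth, annotation, sim)
    footprints = {
        cls: simulate_footprints(truth, annotation, sim, cls) for cls in sorted(FOOTPRINT_CLASSES)
    }
    rng = np.random.default_rng(sim.seed + 40)
    abundances = pd.Series(
        rng.uniform(200, 2000, size=len(annotation)), index=annotation.transcript_id
    )
    rna = simulate_rnaseq(annotation, abundances, sim.seed + 41, sim.rna_abundance_dispersion)
    track = simulate_pars_track(
        annotation, truth, config.pars_baseline, config.pars_site_boost, sim.seed + 42
    )
    dlr = simulate_reporter_table(
        {**config.true_readthrough, **config.true_frameshift, "frame0": 100.0},
        noise_cv=0.0,
        seed=sim.seed + 43,
    )
    qpcr = simulate_qpcr_table(
        {"GRX2": [1.0, 2.0, 4.0, 2.0, 1.0], "ACT1": [2.0, 2.0, 2.0, 2.0, 2.0]},
        {"GRX2": 2.0, "ACT1": 1.9, "spike": 2.0},
        seed=sim.seed + 44,
    )

    formats_io.write_fasta(sequences, outdir / "transcriptome.fa")
    formats_io.write_annotation(annotation, outdir / "annotation.tsv")
    formats_io.write_table(truth_table(truth), outdir / "truth.tsv")
    formats_io.write_bed6c(reads, outdir / "clip_reads.bed6c")
    for cls, fp in footprints.items():
        formats_io.write_bed6(fp, outdir / f"footprints_{cls}.bed")
    formats_io.write_table(rna, outdir / "rna_counts.tsv")
    formats_io.write_table(track, outdir / "pars_track.tsv")
    formats_io.write_table(dlr, outdir / "dlr.tsv")
    formats_io.write_table(qpcr, outdir / "qpcr.tsv")
    provenance["stages"]["simulate"] = {
        "n_transcripts": len(annotation),
        "n_sites": len(truth),
        "n_clip_reads": len(reads),
        **{f"n_footprints_{cls}": len(fp) for cls, fp in footprints.items()},
    }

    # --- call sites -------------------------------------------------------
    sites = call_sites_from_reads(reads, config.call)
    provenance["stages"]["call_sites"] = dict(sites.attrs.get("filter_counts", {}))

    # --- annotate ---------------------------------------------------------
    models = annotate_targets.models_from_annotation(annotation)
    sites = annotate_targets.annotate_sites(sites, models)
    formats_io.write_sites(sites, outdir / "sites.bed")
    targets = annotate_targets.define_targets(sites)
    region = annotate_targets.region_distribution(sites) if len(sites) else pd.Series(dtype=float)
    provenance["stages"]["annotate"] = {
        "n_sites": len(sites),
        "n_targets": len(targets),
        "region_distribution": {k: round(v, 6) for k, v in region.items()},
    }

    # --- quant ------------------------------------------------------------
    expr = quant.build_expression_table(
        annotation,
        clip_counts=quant.clip_reads_in_clusters(reads, sites),
        rna_counts=rna.set_index("transcript_id")["count"],
        rpf_standard_counts=quant.count_reads_per_transcript(
            metagene.filter_class(footprints["standard"], "standard")
        ),
        rpf_short_counts=quant.count_reads_per_transcript(
            metagene.filter_class(footprints["short"], "short")
        ),
        disome_counts=quant.count_reads_per_transcript(
            metagene.filter_class(footprints["disome"], "disome")
        ),
        rna_floor=config.rna_floor,
    )
    formats_io.write_table(expr.round(6), outdir / "expression.tsv")
    provenance["stages"]["quant"] = {"n_transcripts": len(expr)}

    # --- metagene ---------------------------------------------------------
    site_positions = [(r.chrom, int(r.mode_location)) for r in sites.itertuples(index=False)]
    centile = metagene.centile_profile(site_positions, models)
    formats_io.write_table(centile.to_frame().round(6), outdir / "metagene_centile.tsv")
    mode_profiles = {}
    for cls in sorted(FOOTPRINT_CLASSES):
        prof = metagene.mode_centered_density(
            metagene.filter_class(footprints[cls], cls),
            site_positions,
            models,
            halfwidth=config.halfwidth,
        )
        mode_profiles[cls] = prof
        formats_io.write_table(prof.to_frame().round(6), outdir / f"metagene_mode_{cls}.tsv")
    provenance["stages"]["metagene"] = {
        "mean_centile": round(metagene.profile_mean_centile(centile), 3),
        **{
            f"peak_offset_{cls}": metagene.profile_peak_offset(prof)
            for cls, prof in mode_profiles.items()
        },
    }

    # --- framing ----------------------------------------------------------
    hits = []
    for row in sites.itertuples(index=False):
        hits.extend(
            framing_structure.scan_motif(
                sequences[row.chrom], (int(row.start), int(row.end)), config.motif_pattern, row.chrom
            )
        )
    framing_info: dict = {"n_hits": len(hits)}
    if hits:
        try:
            frames, skipped = framing_structure.frame_distribution(hits, models)
            baseline = framing_structure.orfome_frame_baseline(
                sequences, models, config.motif_pattern
            )
            framing_info.update(
                {
                    "site_frames": {int(k): round(v, 6) for k, v in frames.items()},
                    "orfome_frames": {int(k): round(v, 6) for k, v in baseline.items()},
                    "n_out_of_orf": skipped,
                }
            )
            formats_io.write_table(
                pd.DataFrame(
                    {"frame": [0, 1, 2], "sites": frames.values, "orfome": baseline.values}
                ).round(6),
                outdir / "framing.tsv",
            )
        except ValueError:
            framing_info["site_frames"] = None
    provenance["stages"]["framing"] = framing_info

    # --- structure --------------------------------------------------------
    pars = framing_structure.pars30_site_table(track, site_positions, models)
    formats_io.write_table(pars.round(6), outdir / "pars30.tsv")
    provenance["stages"]["structure"] = {
        "n_sites": len(pars),
        "median_site_minus_flank": round(
            float((pars["site"] - (pars["upstream"] + pars["downstream"]) / 2).median()), 6
        )
        if len(pars)
        else None,
    }

    # --- reporters / qpcr -------------------------------------------------
    rt = reporter_quant.readthrough_percent(dlr)
    fs = reporter_quant.frameshift_percent(dlr)
    formats_io.write_table(pd.concat([rt, fs], ignore_index=True).round(6), outdir / "dlr_summary.tsv")
    fractions = reporter_quant.qpcr_fraction_table(qpcr)
    formats_io.write_table(fractions.round(6), outdir / "qpcr_fractions.tsv")
    provenance["stages"]["reporters"] = {
        "readthrough_percent": {r.reporter: round(r.percent, 6) for r in rt.itertuples(index=False)},
        "frameshift_percent": {r.reporter: round(r.percent, 6) for r in fs.itertuples(index=False)},
    }

    with open(outdir / "provenance.json", "w") as handle:
        json.dump(provenance, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return outdir


def demo(seed: int, outdir: str | Path) -> Path:
    """One-command synthetic demo with the default study conditions."""
    config = RunConfig(seed=seed, sim=SimConfig(motif_insertion_frame=0, seed=seed))
    return run_pipeline(config, outdir)
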