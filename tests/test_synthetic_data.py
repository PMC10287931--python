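import io

import numpy as np
import pytest
from scipy import stats

from larpmap import formats_io as fio
from larpmap import synthetic_data as sd


class TestTranscriptome:
    def test_empty_request_gives_empty_outputs(self):
        seqs, ann = sd.generate_transcriptome(sd.SimConfig(n_transcripts=0, n_sites=0))
        assert seqs == {} and len(ann) == 0

    def test_fixed_orf_length_and_codon_structure(self):
        cfg = sd.SimConfig(n_transcripts=5, orf_length_range=(30, 30), seed=2)
        seqs, ann = sd.generate_transcriptome(cfg)
        for row in ann.itertuples(index=False):
            orf = seqs[row.transcript_id][row.orf_start : row.orf_end]
            assert len(orf) == 30 and len(orf) % 3 == 0
            assert orf.startswith("ATG") and orf[-3:] in sd.STOP_CODONS
            internal = [orf[i : i + 3] for i in range(3, len(orf) - 3, 3)]
            assert not any(c in sd.STOP_CODONS for c in internal)

    def test_degenerate_range_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.SimConfig(orf_length_range=(300, 200)).validate()

    def test_seed_determinism_is_byte_identical(self, tmp_path):
        streams = []
        for _ in range(2):
            cfg = sd.SimConfig(seed=7)
            seqs, ann = sd.generate_transcriptome(cfg)
            truth, seqs = sd.plant_sites(ann, seqs, cfg)
            reads = sd.simulate_parclip_reads(truth, ann, cfg)
            fa, bed = tmp_path / "a.fa", tmp_path / "a.bed6c"
            fio.write_fasta(seqs, fa)
            fio.write_bed6c(reads, bed)
            streams.append(fa.read_bytes() + bed.read_bytes())
        assert streams[0] == streams[1]


def _centiles(truth, annotation):
    ann = annotation.set_index("transcript_id")
    out = []
    for t in truth:
        row = ann.loc[t.transcript_id]
        out.append((t.crosslink_pos - row.orf_start) / (row.orf_end - row.orf_start))
    return np.asarray(out)


class TestPlantedSites:
    def test_zero_bias_positions_uniform(self):
        cfg = sd.SimConfig(
            n_transcripts=50, n_sites=2000, site_positional_bias=0.0,
            min_site_separation=0, seed=0,
        )
        seqs, ann = sd.generate_transcriptome(cfg)
        truth, _ = sd.plant_sites(ann, seqs, cfg)
        counts, _ = np.histogram(_centiles(truth, ann), bins=10, range=(0, 1))
        assert stats.chisquare(counts).pvalue > 0.01

    def test_cubic_bias_skews_to_orf_3prime_end(self):
        # density x^3 has mean 4/5, so the mean centile should sit near 80
        cfg = sd.SimConfig(
            n_transcripts=50, n_sites=2000, site_positional_bias=3.0,
            min_site_separation=0, seed=0,
        )
        seqs, ann = sd.generate_transcriptome(cfg)
        truth, _ = sd.plant_sites(ann, seqs, cfg)
        mean_centile = 100 * _centiles(truth, ann).mean()
        assert mean_centile > 60
        assert abs(mean_centile - 80) < 5

    def test_negative_bias_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.SimConfig(site_positional_bias=-1.0).validate()

    def test_motif_written_at_requested_frame(self, motif_sim):
        _, sequences, annotation, truth, _ = motif_sim
        ann = annotation.set_index("transcript_id")
        for t in truth:
            assert t.motif_present and t.motif_frame == 0
            g_pos = t.crosslink_pos - 2
            word = sequences[t.transcript_id][g_pos - 1 : g_pos + 3]
            assert word[0] in "CT" and word[1] == "G" and word[2] in "GC" and word[3] == "T"
            assert (g_pos - ann.loc[t.transcript_id].orf_start) % 3 == 0

    def test_crosslink_base_is_t(self, small_sim):
        _, sequences, _, truth, _ = small_sim
        for t in truth:
            assert sequences[t.transcript_id][t.crosslink_pos] == "T"


class TestClipReads:
    def test_zero_depth_zero_background_empty(self, small_sim):
        cfg, _, annotation, truth, _ = small_sim
        cfg0 = sd.SimConfig(depth_per_site=0.0, background_read_fraction=0.0, seed=1)
        reads = sd.simulate_parclip_reads(truth, annotation, cfg0)
        assert len(reads) == 0

    def test_full_conversion_rate_marks_every_site_read(self, small_sim):
        cfg, _, annotation, truth, _ = small_sim
        cfg1 = sd.SimConfig(conversion_rate=1.0, background_read_fraction=0.0, seed=1)
        reads = sd.simulate_parclip_reads(truth, annotation, cfg1)
        positions = {(t.transcript_id, t.crosslink_pos) for t in truth}
        for row in reads.itertuples(index=False):
            conv = [row.start + o for o in row.conversions]
            assert any((row.chrom, p) in positions for p in conv)

    def test_total_site_reads_within_poisson_error(self):
        # 20 sites at expected depth 50 -> Poisson sum mean 1000, sd ~31.6
        cfg = sd.SimConfig(background_read_fraction=0.0, seed=5)
        seqs, ann = sd.generate_transcriptome(cfg)
        truth, seqs = sd.plant_sites(ann, seqs, cfg)
        reads = sd.simulate_parclip_reads(truth, ann, cfg)
        mean = cfg.depth_per_site * len(truth)
        assert abs(len(reads) - mean) < 3 * np.sqrt(mean)

    def test_conversion_fraction_monotone_in_rate(self):
        cfg = sd.SimConfig(
            n_transcripts=10, n_sites=40, depth_per_site=300.0,
            background_read_fraction=0.0, min_site_separation=20, seed=3,
        )
        seqs, ann = sd.generate_transcriptome(cfg)
        truth, seqs = sd.plant_sites(ann, seqs, cfg)
        fractions = []
        for rate in (0.1, 0.3, 0.5, 0.9):
            cfg_r = sd.SimConfig(
                n_transcripts=10, n_sites=40, depth_per_site=300.0,
                background_read_fraction=0.0, min_site_separation=20,
                conversion_rate=rate, seed=3,
            )
            reads = sd.simulate_parclip_reads(truth, ann, cfg_r)
            assert len(reads) >= 10_000
            fractions.append((reads["conversions"].map(len) > 0).mean())
        assert all(a <= b for a, b in zip(fractions, fractions[1:]))

    def test_background_reads_carry_no_conversions(self, small_sim):
        _, _, _, _, reads = small_sim
        background = reads[reads["name"].str.startswith("bg_")]
        assert len(background) > 0
        assert (background["conversions"].map(len) == 0).all()


class TestFootprints:
    def test_class_length_ranges(self, small_sim):
        cfg, _, annotation, truth, _ = small_sim
        for cls, (lo, hi) in sd.FOOTPRINT_CLASSES.items():
            fp = sd.simulate_footprints(truth, annotation, cfg, cls)
            lengths = fp["end"] - fp["start"]
            assert lengths.between(lo, hi).all()

    def test_unknown_class_rejected(self, small_sim):
        cfg, _, annotation, truth, _ = small_sim
        with pytest.raises(sd.ConfigError):
            sd.simulate_footprints(truth, annotation, cfg, "tetrasome")

    def test_zero_jitter_zero_offset_centers_on_crosslink(self, small_sim):
        _, _, annotation, truth, _ = small_sim
        cfg = sd.SimConfig(
            footprint_offsets={"disome": 0}, footprint_jitter_sd=0.0,
            footprint_background_fraction=0.0, seed=4,
        )
        fp = sd.simulate_footprints(truth, annotation, cfg, "disome")
        positions = {t.transcript_id: [] for t in truth}
        for t in truth:
            positions[t.transcript_id].append(t.crosslink_pos)
        for row in fp.itertuples(index=False):
            center = (row.start + row.end) // 2
            assert any(abs(center - p) <= 1 for p in positions[row.chrom])


class TestAuxiliarySimulators:
    def test_rnaseq_zero_abundance_zero_counts(self, small_sim):
        _, _, annotation, _, _ = small_sim
        counts = sd.simulate_rnaseq(annotation, {}, seed=0)
        assert (counts["count"] == 0).all()

    def test_rnaseq_negative_abundance_rejected(self, small_sim):
        _, _, annotation, _, _ = small_sim
        tid = annotation.iloc[0].transcript_id
        with pytest.raises(sd.ConfigError):
            sd.simulate_rnaseq(annotation, {tid: -5.0}, seed=0)

    def test_pars_track_without_boost_is_baseline(self, small_sim):
        _, _, annotation, truth, _ = small_sim
        track = sd.simulate_pars_track(annotation, truth, baseline=0.7, site_boost=0.0, seed=0)
        assert np.allclose(track["score"], 0.7)

    def test_pars_track_elevated_at_sites(self, small_sim):
        _, _, annotation, truth, _ = small_sim
        track = sd.simulate_pars_track(annotation, truth, baseline=0.5, site_boost=2.0, seed=0)
        t = truth[0]
        sub = track[track.transcript_id == t.transcript_id].set_index("pos")
        assert sub.loc[t.crosslink_pos, "score"] == pytest.approx(2.5)
        assert sub.loc[t.crosslink_pos + 40, "score"] == pytest.approx(0.5)

    def test_qpcr_doubling_gives_one_cycle_per_twofold(self):
        table = sd.simulate_qpcr_table(
            {"g": [1.0, 1.0, 2.0]}, {"g": 2.0, "spike": 2.0}, seed=0
        )
        cq = table["cq"].to_numpy()
        assert cq[0] == pytest.approx(cq[1])
        assert cq[0] - cq[2] == pytest.approx(1.0)

    def test_reporter_zero_noise_encodes_exact_ratios(self):
        table = sd.simulate_reporter_table({"UGA": 2.0}, noise_cv=0.0, seed=0)
        caa = table[table.reporter == "CAA"].iloc[0]
        uga = table[table.reporter == "UGA"].iloc[0]
        assert (uga.fluc / uga.rluc) / (caa.fluc / caa.rluc) == pytest.approx(0.02)
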