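import pandas as pd
import pytest

from larpmap import synthetic_data as sd
from larpmap.formats_io import READ_COLUMNS


def make_reads(rows):
    """rows: (chrom, start, end, strand, conversions) tuples -> read table."""
    return pd.DataFrame(
        [(c, s, e, f"r{i}", "0", st, tuple(conv)) for i, (c, s, e, st, conv) in enumerate(rows)],
        columns=READ_COLUMNS,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Default study conditions: 20 transcripts, 20 planted sites, seed 0."""
    cfg = sd.SimConfig(seed=0)
    sequences, annotation = sd.generate_transcriptome(cfg)
    truth, sequences = sd.plant_sites(annotation, sequences, cfg)
    reads = sd.simulate_parclip_reads(truth, annotation, cfg)
    return cfg, sequences, annotation, truth, reads


@pytest.fixture(scope="session")
def motif_sim():
    """Same conditions with a frame-0 YGSU motif written at every site."""
    cfg = sd.SimConfig(motif_insertion_frame=0, seed=0)
    sequences, annotation = sd.generate_transcriptome(cfg)
    truth, sequences = sd.plant_sites(annotation, sequences, cfg)
    reads = sd.simulate_parclip_reads(truth, annotation, cfg)
    return cfg, sequences, annotation, truth, reads
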