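import pytest

from hifbind.intervals_io import GenomicInterval, Peak, TssRecord
from hifbind.synthetic_data import SynthConfig, generate_dataset

# a small, fast study used across the suite; statistical structure matches the
# full-size defaults, only the sizes are reduced
SMALL_CONFIG = dict(
    seed=11,
    n_genes=400,
    n_chroms=2,
    chrom_length=3_000_000,
    n_peaks_a=800,
    n_peaks_b=600,
)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    cfg = SynthConfig(**SMALL_CONFIG)
    return generate_dataset(cfg, tmp_path_factory.mktemp("bundle"))


def make_peak(chrom, start, end, name="p", height=1.0, summit=None):
    return Peak(GenomicInterval(chrom, start, end), name, height, summit)


def make_tss(gene_id, chrom="chr1", strand="+", tss=10_000, biotype="coding"):
    return TssRecord(gene_id, gene_id, chrom, strand, tss, biotype)
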