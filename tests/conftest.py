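import numpy as np
import pytest

from covmine import (
    CoverageTrack,
    GenomicInterval,
    TrackKind,
    backend_for,
    read_annotation,
)
from covmine.simulate import SimulationConfig, simulate


def make_track(values, start=0, chrom="chr1", strand="+", kind=TrackKind.COUNTS,
               sample="s1"):
    values = np.asarray(values, dtype=float)
    region = GenomicInterval(chrom, start, start + len(values), strand)
    return CoverageTrack(region, [sample], values[None, :], kind)


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """A small but complete simulated experiment shared across tests."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimulationConfig(
        seed=17, n_genes=8, n_samples=3, chrom_length=800_000,
        exons_per_gene=(2, 4),
    )
    manifest = simulate(cfg, outdir)
    return manifest


@pytest.fixture(scope="session")
def accept_sim(tmp_path_factory):
    """The full-size study conditions: 50 genes, 6 samples, defaults."""
    outdir = tmp_path_factory.mktemp("accept_sim")
    return simulate(SimulationConfig(seed=29), outdir)


@pytest.fixture(scope="session")
def sim_annotation(sim):
    return sim.annotation()


@pytest.fixture(scope="session")
def sim_bam_sources(sim):
    return {
        s: backend_for(sim.files[s]["bam"], s).source() for s in sim.samples
    }


@pytest.fixture(scope="session")
def sim_tsv_sources(sim):
    return {
        s: backend_for(sim.files[s]["read_tsv"], s).source() for s in sim.samples
    }
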