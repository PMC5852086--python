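"""Shared fixtures: all test data is generated programmatically."""

import pytest

from eccseq.cli import run_detection
from eccseq.config import DetectionConfig
from eccseq.synthetic_data import plant_circles, simulate_dna_reads, simulate_genome


@pytest.fixture
def cfg():
    return DetectionConfig(seed=0)


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome random genome."""
    genome, index = simulate_genome([300_000, 150_000], gc_content=0.45, seed=11)
    return genome, index


@pytest.fixture(scope="session")
def clean_sample():
    """A clean simulated sample: 20 planted circles, 20x internal depth,
    zero background, plus its detection results."""
    genome, index = simulate_genome([1_000_000, 500_000], seed=7)
    truth = plant_circles(genome, index, 20, seed=7)
    reads = simulate_dna_reads(
        truth, internal_depth=20, junction_read_min=3, background_depth=0, seed=7
    )
    aln = reads.alignment_set()
    cfg = DetectionConfig(seed=7)
    calls, report = run_detection(aln, cfg, reference=genome)
    return {
        "genome": genome,
        "index": index,
        "truth": truth,
        "reads": reads,
        "alignments": aln,
        "cfg": cfg,
        "calls": calls,
        "report": report,
    }
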