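import numpy as np
import pytest

from esdeg.motifs import PositionCountMatrix, pcm_to_pwm
from esdeg.promoters import PromoterRecord, PromoterSet
from esdeg.synthetic import SimulationConfig, random_pcm, simulate_promoters


@pytest.fixture
def consensus_pcm():
    """Sharply informative 6-bp motif with consensus ACGTGA."""
    counts = np.full((6, 4), 1.0)
    for i, base in enumerate("ACGTGA"):
        counts[i, "ACGT".index(base)] = 97.0
    return PositionCountMatrix(motif_id="CONS", counts=counts)


@pytest.fixture
def consensus_pwm(consensus_pcm):
    return pcm_to_pwm(consensus_pcm)


@pytest.fixture
def random_pwm():
    return pcm_to_pwm(random_pcm("RND", 8, seed=123, concentration=0.3))


@pytest.fixture
def small_universe():
    """200 uniform-background promoters of 100 bp."""
    config = SimulationConfig(n_genes=200, promoter_length=100, seed=77)
    return simulate_promoters(config)


def make_promoter(gene_id: str, sequence: str, strand: str = "+") -> PromoterRecord:
    return PromoterRecord(
        gene_id=gene_id,
        chrom="chrT",
        strand=strand,
        window_start=0,
        window_end=len(sequence),
        sequence=sequence,
    )


@pytest.fixture
def promoter_factory():
    return make_promoter


def promoter_set_from_sequences(sequences: dict[str, str]) -> PromoterSet:
    return PromoterSet([make_promoter(g, s) for g, s in sequences.items()])
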