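from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

from spinqc.synthetic_data import (
    make_reference_proteome,
    make_transcriptome,
    simulate_blast_tables,
)

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset shared across module tests.

    10 reference genes, 25 loci x 2 isoforms = 50 transcripts; the 10
    first-isoform core transcripts are planted orthologs, everything else
    a paralog. BLAST tables carry decoys and planted OHR values.
    """
    proteins, db = make_reference_proteome(10, seed=11)
    transcripts, gt = make_transcriptome(
        proteins, n_loci=25, isoforms_per_locus=2, seed=11
    )
    fwd, rev = simulate_blast_tables(gt, db, decoy_rate=0.5, seed=11)
    return SimpleNamespace(
        proteins=proteins,
        db=db,
        transcripts=transcripts,
        gt=gt,
        fwd=fwd,
        rev=rev,
    )
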