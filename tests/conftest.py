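import pytest

from netdlnc.synthetic_data import SimulationConfig


@pytest.fixture
def config():
    """Default study conditions, seed 1."""
    return SimulationConfig(seed=1)


@pytest.fixture
def small_config():
    """Reduced transcript count for fast unit tests."""
    return SimulationConfig(
        seed=1,
        n_transcripts=120,
        n_planted_per_class=10,
        signature_size=10,
        n_outcome_planted=2,
        n_outcome_samples=60,
    )


@pytest.fixture
def toy_gtf(tmp_path):
    """Three-transcript GTF: one antisense, one lincRNA, one IG_C_pseudogene."""
    lines = [
        'chr1\tens\ttranscript\t101\t500\t.\t+\t.\tgene_name "ASX"; transcript_id "T1"; transcript_biotype "antisense";',
        'chr1\tens\texon\t101\t200\t.\t+\t.\tgene_name "ASX"; transcript_id "T1"; transcript_biotype "antisense";',
        'chr1\tens\texon\t301\t500\t.\t+\t.\tgene_name "ASX"; transcript_id "T1"; transcript_biotype "antisense";',
        'chr2\tens\texon\t11\t400\t.\t-\t.\tgene_name "LINCY"; transcript_id "T2"; transcript_biotype "lincRNA";',
        'chr3\tens\texon\t1\t90\t.\t+\t.\tgene_name "IGPZ"; transcript_id "T3"; transcript_biotype "IG_C_pseudogene";',
    ]
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
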