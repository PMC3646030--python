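import pytest

from msiseq import SimParams, annotate, generate_sample, generate_transcriptome, score_sample

SMALL = dict(n_transcripts=25, transcript_len=600)


@pytest.fixture(scope="session")
def small_transcriptome():
    """A small but fully structured transcriptome shared across tests."""
    return generate_transcriptome(SimParams(seed=11, **SMALL))


@pytest.fixture(scope="session")
def default_transcriptome():
    """Default-scale transcriptome used by the simulation-heavy tests."""
    return generate_transcriptome(SimParams(seed=7))


def score_simulated(transcriptome, params, sample_id=None):
    """Generate a sample and push it through annotate -> profile -> classify."""
    sample = generate_sample(params, transcriptome, sample_id=sample_id)
    annotated = annotate(sample.calls, transcriptome.catalogue, transcriptome.models)
    profile, result = score_sample(annotated, sample.sample_id)
    return sample, profile, result
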