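import pytest
from hypothesis import HealthCheck, settings

from anchora import GeneLists, GeneSetCollection, PipelineConfig, TranscriptRecord

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_lists(background, deregulated, transcripts=None):
    return GeneLists(
        background=frozenset(background),
        deregulated=frozenset(deregulated),
        transcripts=transcripts or [],
    )


def make_collection(db, terms, background):
    """terms: {term_id: iterable of genes} (names auto-filled)."""
    return GeneSetCollection(
        db, {t: (f"name of {t}", frozenset(g)) for t, g in terms.items()}, background
    )


@pytest.fixture
def default_cfg():
    return PipelineConfig()


@pytest.fixture
def tiny_lists():
    recs = [
        TranscriptRecord("t1", "g1", bmd=2.0, trend="inc"),
        TranscriptRecord("t2", "g1", bmd=6.0, trend="dec"),
        TranscriptRecord("t3", "g2", bmd=4.0, trend="dec"),
    ]
    return make_lists(
        ["g1", "g2", "g3", "g4"], ["g1", "g2"], transcripts=recs
    )
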