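import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from summdiv import SummaryCorpus, SummaryDocument


def make_corpus(entries):
    """Corpus from (timeline_id, system_id, text) triples."""
    return SummaryCorpus(
        SummaryDocument(timeline_id=t, system_id=s, text=text)
        for t, s, text in entries
    )


@pytest.fixture
def two_system_corpus():
    """Three timelines, two systems, small distinct texts."""
    return make_corpus(
        [
            ("t1", "human", "the cat sat on the mat"),
            ("t2", "human", "a dog ran in the park"),
            ("t3", "human", "birds sing at dawn every day"),
            ("t1", "model", "the cat sat on the mat today"),
            ("t2", "model", "the cat sat near the mat"),
            ("t3", "model", "the cat sat by a mat"),
        ]
    )
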