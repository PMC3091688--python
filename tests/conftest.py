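from __future__ import annotations

import pytest

from hbcluster.pipeline import annotate_sequence
from hbcluster.simulate import chr6_config, generate_cluster, make_templates


@pytest.fixture(scope="session")
def templates():
    return make_templates(2010)


@pytest.fixture(scope="session")
def chr6_cluster(templates):
    """Canonical chromosome-6-like synthetic cluster (seed 1)."""
    return generate_cluster(chr6_config(1), templates)


@pytest.fixture(scope="session")
def annotated_chr6(templates, chr6_cluster):
    seq, _ = chr6_cluster
    return annotate_sequence(seq, templates, chromosome_label="Chr6")
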