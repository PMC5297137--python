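import numpy as np
import pytest
from hypothesis import settings

import linkvar as lv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return lv.IdentifierSchema()


def _pair(bits, **kw):
    return lv.ComparisonPair(pattern=lv.AgreementPattern(bits), **kw)


@pytest.fixture(scope="session")
def tiny_pairs():
    """Twelve hand-countable labelled pairs.

    Matches: 3x{111}, 2x{110}, 1x{011}.  Non-matches: 1x{110}, 2x{010},
    2x{000}, 1x{100}.  Per-identifier agreement among the 6 matches:
    dob 5, sex 6, postcode 4; among the 6 non-matches: dob 2, sex 3, pc 0.
    """
    m = [_pair((1, 1, 1), is_match=True) for _ in range(3)]
    m += [_pair((1, 1, 0), is_match=True) for _ in range(2)]
    m += [_pair((0, 1, 1), is_match=True)]
    u = [_pair((1, 1, 0), is_match=False)]
    u += [_pair((0, 1, 0), is_match=False) for _ in range(2)]
    u += [_pair((0, 0, 0), is_match=False) for _ in range(2)]
    u += [_pair((1, 0, 0), is_match=False)]
    return m + u


@pytest.fixture(scope="session")
def medium_population():
    """A moderately sized synthetic extract shared across tests."""
    cfg = lv.GeneratorConfig(n_individuals=60_000, n_hospitals=25, seed=202)
    pairs, admissions = lv.generate_population(cfg)
    return cfg, pairs, admissions
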