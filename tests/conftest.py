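import warnings

import pytest

from puctools import synthetic

# Biopython 1.88 renamed the end-gap score attributes; the aligner handles
# both spellings, the deprecation chatter is just noise in test output.
warnings.filterwarnings("ignore", message=".*end_gap_score.*")
warnings.filterwarnings("ignore", category=DeprecationWarning, module="Bio")


@pytest.fixture(scope="session")
def refset() -> synthetic.ReferenceSet:
    return synthetic.make_reference_set(11)


@pytest.fixture(scope="session")
def cga009_dataset(refset):
    """Reference-strain-patterned synthetic genome with annotations + truth."""
    cfg = synthetic.cga009_pattern(seed=5)
    genome, features, truth = synthetic.generate_genome(cfg, refset)
    return cfg, genome, features, truth
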