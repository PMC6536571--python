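import logging

import numpy as np
import pytest

from ctdnaflow.calls import VariantCall, balanced_call
from ctdnaflow.synthetic import CohortConfig, generate_full_cohort

logging.getLogger("ctdnaflow").setLevel(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-scale synthetic cohort with raw calls attached."""
    cohort, whitelist = generate_full_cohort(CohortConfig(seed=7))
    return cohort, whitelist


def make_call(
    vaf: float = 0.05,
    depth: int = 12_000,
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "T",
    p_value: float = 1e-9,
    **kwargs,
) -> VariantCall:
    """Strand-balanced call with the requested VAF."""
    return balanced_call(
        chrom, pos, ref, alt, depth=depth, alt_count=round(vaf * depth),
        p_value=p_value, **kwargs,
    )
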