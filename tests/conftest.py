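import numpy as np
import pandas as pd
import pytest

from nerkasweep.alignment import AlignmentScoring, PairwiseAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_alignment(a_gapped: str, b_gapped: str, score: float = 0.0) -> PairwiseAlignment:
    """Build a PairwiseAlignment directly from gapped strings (test helper)."""
    return PairwiseAlignment(
        a_gapped=a_gapped, b_gapped=b_gapped, score=score, scoring=AlignmentScoring()
    )


def miscall_table() -> pd.DataFrame:
    """Genotype table realizing the five-system miscall counts: one GG among
    238 stream-labelled fish, four GT (and no TT) among 336 shore-labelled."""
    rows = []

    def add(pop, ecotype, genotype, count):
        start = len(rows)
        for i in range(count):
            rows.append(
                {
                    "sample_id": f"{pop}_{start + i:04d}",
                    "population": pop,
                    "ecotype": ecotype,
                    "genotype": genotype,
                }
            )

    # shore pool: Okanagan 144, Christina 48, Anderson 22, Seton 23, Redfish 99 = 336
    add("Okanagan Lake", "shore", "GG", 140)
    add("Okanagan Lake", "shore", "GT", 4)
    add("Christina Lake", "shore", "GG", 48)
    add("Anderson Lake", "shore", "GG", 22)
    add("Seton Lake", "shore", "GG", 23)
    add("Redfish Lake", "shore", "GG", 99)
    # stream pool: Mission 136, Sanders 48, Portage 20, Fishhook 34 = 238
    add("Mission Creek", "stream", "TT", 100)
    add("Mission Creek", "stream", "GT", 35)
    add("Mission Creek", "stream", "GG", 1)
    add("Sanders Creek", "stream", "TT", 48)
    add("Portage Creek", "stream", "GT", 20)
    add("Fishhook Creek", "stream", "TT", 34)
    return pd.DataFrame(rows)


FIVE_SYSTEMS = [
    "Okanagan Lake",
    "Christina Lake",
    "Anderson Lake",
    "Seton Lake",
    "Redfish Lake",
    "Mission Creek",
    "Sanders Creek",
    "Portage Creek",
    "Fishhook Creek",
]
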