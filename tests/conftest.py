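from __future__ import annotations

import pytest

from declust.model import GeneAnnotation, ThresholdConfig


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


def make_annotations(n: int, strand: str = "+", prefix: str = "G") -> dict[str, GeneAnnotation]:
    """n unit-spaced genes G1..Gn on one strand."""
    return {
        f"{prefix}{i + 1}": GeneAnnotation(
            locus_tag=f"{prefix}{i + 1}",
            start=i * 100 + 1,
            end=i * 100 + 90,
            strand=strand,
            ordinal=i,
        )
        for i in range(n)
    }


@pytest.fixture
def annotations10() -> dict[str, GeneAnnotation]:
    return make_annotations(10)
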