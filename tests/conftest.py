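import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ampligauge.taxonomy import (
    Rank,
    RankedLineage,
    TrainingRecord,
    TrainingSet,
    normalize_lineage,
)


def make_lineage(
    genus: str,
    family: str = "F1",
    order: str = "O1",
    klass: str = "C1",
    phylum: str = "P1",
    species: str | None = None,
    gap_order_family: bool = False,
) -> RankedLineage:
    raw = [("Bacteria", Rank.DOMAIN), (phylum, Rank.PHYLUM), (klass, Rank.CLASS)]
    if not gap_order_family:
        raw += [(order, Rank.ORDER), (family, Rank.FAMILY)]
    raw.append((genus, Rank.GENUS))
    return normalize_lineage(raw, species=species)


@pytest.fixture
def two_genus_model():
    """Two genera in one family with disjoint word sets."""
    from ampligauge.nbc import train

    ts = TrainingSet(
        (
            TrainingRecord("a", "ACGTACGTA", make_lineage("G1")),
            TrainingRecord("b", "TTTTTTTTT", make_lineage("G2")),
        )
    )
    return train(ts), ts
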