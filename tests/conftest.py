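import numpy as np
import pytest

from buffercrops import (
    ArchContext,
    BinSpec,
    ManorRecord,
    SynthConfig,
    aggregate_bins,
    gen_climate,
    gen_contexts,
)


@pytest.fixture(scope="session")
def default_spec() -> BinSpec:
    return BinSpec()


@pytest.fixture(scope="session")
def synth_bundle(default_spec):
    """One default synthetic dataset binned and ready for association."""
    cfg = SynthConfig(seed=42)
    varve, cit = gen_climate(cfg)
    contexts = gen_contexts(cfg, (varve, cit))
    series = aggregate_bins(contexts, default_spec)
    return cfg, varve, cit, contexts, series


@pytest.fixture
def simple_contexts() -> list[ArchContext]:
    def ctx(i, early, late, **counts):
        return ArchContext(
            site_id=f"S{i}", context_id=f"C{i}", date_early=early,
            date_late=late, counts=counts,
        )

    return [
        ctx(1, 300, 400, rye=3, millet=7),
        ctx(2, 310, 390, rye=10),
        ctx(3, 350, 370, millet=5),
        ctx(4, 500, 560, rye=6, oat=4),
    ]


@pytest.fixture
def manor_records() -> list[ManorRecord]:
    def rec(i, year, present_hemp=False, **sown):
        return ManorRecord(manor_id=f"M{i}", year=year, sown=sown)

    return [
        rec(1, 1550, rye=10.0, oat=6.0, buckwheat=2.0, millet=1.0, hemp=1.0),
        rec(2, 1560, rye=4.0, oat=6.0),
        rec(3, 1590, rye=12.0, oat=6.0, buckwheat=2.0),
        rec(4, 1520, rye=8.0, oat=8.0),
        rec(5, 1650, rye=9.0, oat=5.0, buckwheat=1.0),
        rec(6, 1660, rye=7.0, oat=3.0),
        rec(7, 1680, rye=11.0, oat=4.0, millet=0.5),
        rec(8, 1750, rye=10.0, oat=7.0, buckwheat=1.0),
        rec(9, 1790, rye=6.0, oat=6.0),
        rec(10, 1800, rye=9.0, oat=4.0, hemp=0.5),
    ]
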