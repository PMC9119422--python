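import numpy as np
import pytest

from snpsat.io_formats import VariantRecord
from snpsat.synthetic import SimulationScenario, StrainSpec, default_scenario


@pytest.fixture
def scenario():
    return default_scenario(seed=11)


@pytest.fixture
def one_strain_scenario():
    return SimulationScenario(
        seed=11, strains=[StrainSpec("s", 20_000, 1.0, 120, mu=50.0, sigma=5.0)]
    )


def make_record(pos=100, **kw):
    defaults = dict(
        chrom="chr1",
        pos=pos,
        ref="A",
        alt="G",
        total_depth=30,
        alt_reads=15,
        var_freq=0.5,
        variant_quality=40.0,
        rms_mapq=50.0,
        p_value=0.001,
        caller="test",
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


@pytest.fixture
def record_factory():
    return make_record


def random_records(n, seed, with_effects=False):
    """Records with randomized filter-relevant fields straddling every
    threshold boundary."""
    rng = np.random.default_rng(seed)
    effects = [
        "missense_variant",
        "synonymous_variant",
        "stop_gained",
        "intergenic_region",
        "start_retained_variant",
    ]
    out = []
    for i in range(n):
        depth = int(rng.integers(0, 30))
        alt = int(rng.integers(0, depth + 1))
        rec = VariantRecord(
            chrom="c",
            pos=i + 1,
            ref="A",
            alt="T",
            total_depth=depth,
            alt_reads=alt,
            var_freq=float(rng.uniform(0, 1)),
            variant_quality=float(rng.uniform(0, 30)) if rng.random() > 0.1 else None,
            rms_mapq=float(rng.uniform(0, 30)) if rng.random() > 0.1 else None,
            p_value=float(rng.uniform(0, 0.2)) if rng.random() > 0.1 else None,
            caller="x",
            effect=str(rng.choice(effects)) if with_effects else None,
        )
        out.append(rec)
    return out


@pytest.fixture
def random_record_factory():
    return random_records
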