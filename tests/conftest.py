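import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from silacdyn import (
    GrowthModel,
    ProteinQuant,
    SampleMeta,
    SampleQuant,
)


@pytest.fixture(scope="session")
def study_growth() -> GrowthModel:
    """The study's growth regime: 1.3-fold cell increase over 24 h."""
    return GrowthModel.from_growth_factor(1.3, 24.0)


@pytest.fixture
def metadata_0mM():
    """A control-condition time course with cell counts."""
    td = GrowthModel.from_growth_factor(1.3, 24.0).t_double
    return [
        SampleMeta(sample_id=f"c0_t{t:g}_r1", time_h=t, nacl_mM=0.0,
                   replicate=1, cell_count=1e6 * 2 ** (t / td))
        for t in (1.0, 3.0, 8.0, 24.0)
    ]


def make_protein(pid, mass, blocks):
    """blocks: {sample_id: (ratio, ratio_count, intensity, unique_peptides)}"""
    samples = {
        sid: SampleQuant(ratio_hl=r, ratio_count=rc, intensity=i, unique_peptides=u)
        for sid, (r, rc, i, u) in blocks.items()
    }
    return ProteinQuant(protein_id=pid, molecular_mass=mass, samples=samples)


@pytest.fixture
def three_proteins(metadata_0mM):
    """Three proteins with full time courses, one with a missing ratio."""
    td = GrowthModel.from_growth_factor(1.3, 24.0).t_double
    k_dil = np.log(2) / td
    out = []
    for j, k_deg in enumerate([0.005, 0.0154, 0.05]):
        blocks = {}
        for m in metadata_0mM:
            r = float(np.expm1((k_deg + k_dil) * m.time_h))
            blocks[m.sample_id] = (r, 4, 1e8 * (j + 1), 3)
        out.append(make_protein(f"P{j}", 5e4 * (j + 1), blocks))
    # third protein loses its 8 h point
    sid = "c0_t8_r1"
    out[2].samples[sid] = SampleQuant(ratio_hl=None, ratio_count=0,
                                      intensity=3e8, unique_peptides=3)
    return out
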