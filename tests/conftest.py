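import numpy as np
import pytest

from facemod import synthdata


@pytest.fixture(scope="session")
def template64():
    return synthdata.generate_template_face(64)


@pytest.fixture(scope="session")
def small_study():
    """Three small cohorts with one planted mandibular SNP and two rare SNPs."""
    snps = [synthdata.SnpSpec(f"rs{j}", maf=0.15 + 0.05 * j) for j in range(4)]
    snps.append(synthdata.SnpSpec("rs_rare", maf=0.02))
    snps.append(
        synthdata.SnpSpec("rs_planted", maf=0.25, beta=1.2, target_module="mandible")
    )
    spec = synthdata.SimulationSpec(
        n_subjects=(150, 120, 180),
        n_landmarks=64,
        snp_specs=snps,
        seed=42,
    )
    return synthdata.simulate_study(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
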