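import numpy as np
import pytest

from chd_phonoscreen.synth import SynthSpec, gen_heart_sound


@pytest.fixture(scope="session")
def short_record():
    """8 s normal record with exact fiducials (fast shared fixture)."""
    return gen_heart_sound(SynthSpec(duration=8.0, seed=1))


@pytest.fixture(scope="session")
def short_chd_record():
    return gen_heart_sound(SynthSpec(duration=8.0, seed=2, murmur_kind="systolic"))


@pytest.fixture(scope="session")
def small_cohort():
    """Six 8 s records (alternating classes) with ground truth."""
    out = []
    for i in range(6):
        spec = SynthSpec(duration=8.0, seed=10 + i,
                         murmur_kind="systolic" if i % 2 else "none")
        out.append(gen_heart_sound(spec))
    return out


@pytest.fixture(scope="session")
def fitted_hmm(small_cohort):
    from chd_phonoscreen.pipeline import fit_segmenter
    return fit_segmenter([rec for rec, _ in small_cohort])
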