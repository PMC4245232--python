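import numpy as np
import pytest

import medimeta as mm


@pytest.fixture
def toy_meta():
    return mm.StudyMeta(study_id="toy", control_group="ctrl")


@pytest.fixture
def toy_csv(tmp_path):
    path = tmp_path / "toy.csv"
    path.write_text(
        "animal_id,group,mediator,outcome\n"
        "a1,ctrl,10,5.0\n"
        "a2,ctrl,12,6.5\n"
        "a3,ctrl,11,5.5\n"
        "a4,trt,20,9.0\n"
        "a5,trt,22,8.0\n"
        "a6,trt,18,9.5\n"
    )
    return path


@pytest.fixture
def synthetic_study():
    """A well-behaved two-arm study from the generator's default conditions."""
    return mm.generate_study(mm.SyntheticStudySpec(seed=42))


@pytest.fixture
def standardized_study(synthetic_study):
    return mm.prepare_study(synthetic_study)


@pytest.fixture
def quick_config():
    """Small but adequate sampler settings for unit tests."""
    return mm.MediationConfig(n_chains=3, n_iter=3000, seed=7)


def make_estimates(pairs, quantity="indirect", outcomes=None):
    """EffectEstimates from (study_id, y, v) triples with wide CIs."""
    out = []
    for i, (sid, y, v) in enumerate(pairs):
        out.append(
            mm.EffectEstimate(
                study_id=sid,
                quantity=quantity,
                y=y,
                v=v,
                ci_low=y - 5 * np.sqrt(v),
                ci_high=y + 5 * np.sqrt(v),
                outcome=(outcomes[i] if outcomes else ""),
            )
        )
    return out
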