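import numpy as np
import pytest

import mnarsens as mn


@pytest.fixture(scope="session")
def records():
    """The packaged 36-study attrition table."""
    return mn.load_packaged_attrition_table()


@pytest.fixture(scope="session")
def std_effects(records):
    """Continuity-corrected standard log odds ratios for all 36 studies."""
    return mn.compute_effects(records, "standard", correction=True)


@pytest.fixture(scope="session")
def peto_effects(records):
    """Uncorrected per-study Peto effects (zero-event studies dropped)."""
    return mn.compute_effects(records, "peto", skip_undefined=True)


@pytest.fixture(scope="session")
def mnar_trial():
    """One moderately sized trial with differential MNAR missingness."""
    cfg = mn.TrialSimConfig(
        n_active=400,
        n_passive=200,
        treatment_effect=-0.4,
        mechanism="MNAR_on_posttest",
        mnar_shift=1.0,
        seed=20260901,
    )
    return mn.simulate_trial(cfg)


@pytest.fixture()
def complete_trial():
    """A fully observed trial (no missingness)."""
    cfg = mn.TrialSimConfig(
        n_active=60,
        n_passive=40,
        miss_prob_active=0.0,
        miss_prob_passive=0.0,
        seed=5,
    )
    return mn.simulate_trial(cfg)


def make_trial(pretest, posttest, arm, direction="lower_is_better"):
    pretest = np.asarray(pretest, dtype=float)
    return mn.TrialDataset(
        subject_id=np.arange(len(pretest)),
        arm=np.asarray(arm, dtype=object),
        pretest=pretest,
        posttest=np.asarray(posttest, dtype=float),
        direction=direction,
    )
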