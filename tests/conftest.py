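import numpy as np
import pytest

from varusplan import KneeAlignment


def make_knee(mFTA, mMPTA, mLDFA, JLCA=None, WBL_ratio=None):
    """Knee with consistent defaults: JLCA from the additive model, WBL linearized."""
    if JLCA is None:
        JLCA = mFTA + mMPTA - mLDFA
    if WBL_ratio is None:
        WBL_ratio = min(200.0, max(-100.0, 50.0 - 4.5 * mFTA))
    return KneeAlignment(mFTA=mFTA, mMPTA=mMPTA, mLDFA=mLDFA, JLCA=JLCA, WBL_ratio=WBL_ratio)


@pytest.fixture
def fig2_knee():
    # 6 deg varus, no bony deformity, tibial potential 4.7 vs femoral 4.3
    return make_knee(6.0, 85.3, 89.3, JLCA=2.0)


@pytest.fixture
def fig3_knee():
    # 10 deg varus, tibial deformity, high-normal mLDFA
    return make_knee(10.0, 84.4, 90.0, JLCA=4.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_knees(rng, n):
    """Random physiologic-ish varus knees (mFTA >= 3) for planner properties."""
    mfta = rng.uniform(3.0, 20.0, n)
    mmpta = rng.uniform(76.0, 99.0, n)
    mldfa = rng.uniform(81.0, 99.0, n)
    jlca = rng.uniform(0.0, 8.0, n)
    return [
        make_knee(float(a), float(b), float(c), JLCA=float(d))
        for a, b, c, d in zip(mfta, mmpta, mldfa, jlca)
    ]
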