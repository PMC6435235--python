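"""Shared fixtures: the baseline symmetric parameterization used throughout.

Baseline vital rates (juvenile mortality 0.5, adult mortality 0.1,
maturation 0.5 for both sexes; primary sex ratio 0.5; union reproductive
rate 20) are deliberately sex-symmetric so that any sex-ratio bias in the
output is attributable to mating-system structure or harvest, not to the
vital rates.
"""

import pytest

from bmmr import MatingSpec, ModelParams, make_stage_space

BASELINE = dict(
    mu_m1=0.5, mu_f1=0.5, mu_m2=0.1, mu_f2=0.1,
    alpha_m=0.5, alpha_f=0.5, s1=0.5, k=20.0,
)


@pytest.fixture(scope="session")
def harmonic():
    return MatingSpec()


@pytest.fixture
def monogamy_params():
    return ModelParams(h=1, d=0.1, E=0.0, **BASELINE)


@pytest.fixture
def monogamy_space():
    return make_stage_space(1)


def baseline_params(**overrides) -> ModelParams:
    merged = {**BASELINE, **overrides}
    return ModelParams(**merged)
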