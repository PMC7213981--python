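import pytest

from binddiscard import KineticParams, estimate_kp_from_slope

# central study conditions: ~2000 NICD molecules/nucleus, 120-min basal
# half-life, 8-min phosphorylated half-life, 5.4 endogenous site equivalents
NICD0 = 2000.0
GAMMA_UP = 1.0 / 120.0
GAMMA_P = 1.0 / 8.0
N_E = 5.4
SLOPE_NORM = -0.0294  # measured per-site slope of the normalized reporter curve


@pytest.fixture(scope="session")
def central_params() -> KineticParams:
    return KineticParams(
        NICD0=NICD0, Gamma_up=GAMMA_UP, Gamma_p=GAMMA_P, k_p=0.5, N_e=N_E, N_s=12
    )


@pytest.fixture(scope="session")
def calibrated_kp() -> float:
    """Phosphorylation rate implied by the measured normalized slope."""
    return estimate_kp_from_slope(SLOPE_NORM, NICD0, GAMMA_UP, GAMMA_P, N_E)
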