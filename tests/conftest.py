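import dataclasses

import pytest

from cspfit import reference_fixtures, simulate_titration


def noiseless(spec):
    return dataclasses.replace(spec, noise_sd=0.0)


@pytest.fixture(scope="session")
def fixtures():
    return reference_fixtures()


@pytest.fixture(scope="session")
def recombinant_series(fixtures):
    """Noiseless 10-point single-domain titration plus its ground truth."""
    return simulate_titration(noiseless(fixtures["ww4_smad7_recombinant"]))


@pytest.fixture(scope="session")
def tandem_series(fixtures):
    """Noiseless 10-point tandem two-site titration plus its ground truth."""
    return simulate_titration(noiseless(fixtures["ww34_smad7_tandem"]))
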