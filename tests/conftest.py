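"""Shared fixtures: the two canonical operating points and their adjoints.

The PING circuit (E->I->E loop, drive on the pyramids) and the ING
circuit (I->I loop, drive on both populations) are expensive enough to
build once per session; every test that needs a limit cycle or an iPRC
reuses these.
"""

import pytest

import gammalock as gl


@pytest.fixture(scope="session")
def ping_bundle():
    return gl.figure_preset("fig2_ping")


@pytest.fixture(scope="session")
def ing_bundle():
    return gl.figure_preset("fig3_ing")


@pytest.fixture(scope="session")
def ping_cycle(ping_bundle):
    b = ping_bundle
    return gl.find_limit_cycle(b.e_params, b.i_params, b.couplings, b.drive_values)


@pytest.fixture(scope="session")
def ing_cycle(ing_bundle):
    b = ing_bundle
    return gl.find_limit_cycle(b.e_params, b.i_params, b.couplings, b.drive_values)


@pytest.fixture(scope="session")
def ping_adjoint(ping_cycle):
    return gl.adjoint_iprc(ping_cycle)


@pytest.fixture(scope="session")
def ing_adjoint(ing_cycle):
    return gl.adjoint_iprc(ing_cycle)


@pytest.fixture(scope="session")
def fig5_interaction(ping_adjoint, ping_cycle):
    """H-function at the canonical cross-coupling (G_ee=0.1, G_ie=0.5)."""
    cc = gl.CrossCoupling(g_ee=0.1, g_ie=0.5)
    return gl.interaction_function(ping_adjoint, ping_cycle, cc)
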