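"""Shared fixtures.

The expensive objects (full-model sweeps, delay tables, two-input matrices)
are computed once per session and shared between the unit tests and the
acceptance tests.  Grid sizes are chosen so the whole suite stays at
desk scale while still exercising the documented study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest

import psfkit as pk

# settling criterion tight enough for oracle comparisons at 1e-6 relative
TIGHT = pk.SteadyStateCriterion(rel_change=1e-7, window=200.0, max_time=1e6)

HIGH_CA = 8000.0            # nM; the high-calcium study condition
TABLE_SPECIES = ("DaD1R", "AC5GoaGTP", "AC5CaGoaGTP", "cAMP", "PKAc",
                 "pThr34", "PP2Ap", "PP2Ac", "pThr75")


@pytest.fixture(scope="session")
def striatal() -> pk.ReactionSystem:
    return pk.builtin_striatal_model()


@pytest.fixture(scope="session")
def da_sweep(striatal):
    """Dopamine sweep 100 nM..5 uM (20 log points) under high Ca."""
    return pk.systemic_psf(striatal, "Da", (100.0, 5000.0), n=20,
                           overrides={"Ca": HIGH_CA})


@pytest.fixture(scope="session")
def ca_sweep(striatal):
    """Calcium sweep 100 nM..10 uM (12 log points) with Da held at 5 uM."""
    return pk.systemic_psf(striatal, "Ca", (100.0, 10000.0), n=12,
                           overrides={"Da": 5000.0})


@pytest.fixture(scope="session")
def delay_tab(striatal):
    """Step-response delays for the delay-analysis species under high Ca."""
    system = striatal.with_initial({"Ca": HIGH_CA})
    transitions = [
        pk.StepTransition("Da", 60.0, 500.0),
        pk.StepTransition("Da", 60.0, 4500.0),
        pk.StepTransition("Da", 500.0, 60.0),
        pk.StepTransition("Da", 4500.0, 60.0),
    ]
    return pk.delay_table(system, transitions, list(TABLE_SPECIES))


@pytest.fixture(scope="session")
def two_input_mats(striatal):
    """4x4 Da x Ca psf matrices for the adenylyl-cyclase branch point."""
    g_da = pk.make_grid(100.0, 5000.0, 4)
    g_ca = pk.make_grid(500.0, 10000.0, 4)
    return pk.psf_matrices(striatal, ("Da", "Ca"), (g_da, g_ca),
                           ["AC5GoaGTP", "AC5Ca"])


@pytest.fixture()
def toy_binding_system():
    return pk.make_fixture("toy_binding",
                           {"a_total": 100.0, "b_total": 100.0,
                            "kon": 0.01, "koff": 1.0})
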