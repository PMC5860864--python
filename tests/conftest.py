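"""Shared fixtures: one default-condition simulator and fitted models.

Session-scoped because building the calibrated caller and the trained
aneuploidy classifier is the expensive part; tests treat them as read-only.
"""

import pytest

import uroseek as u


@pytest.fixture(scope="session")
def sim() -> u.CohortSimulator:
    return u.CohortSimulator(u.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def control_panels(sim):
    return sim.control_panels()


@pytest.fixture(scope="session")
def caller(sim, control_panels) -> u.MutationCallerResults:
    wbc, urine = control_panels
    return u.MutationCallerModel(wbc, urine, sim.panel).fit()


@pytest.fixture(scope="session")
def euploid_profiles(sim):
    return sim.euploid_profiles(677)


@pytest.fixture(scope="session")
def aneuploidy_fit(sim, euploid_profiles) -> u.AneuploidyResults:
    return u.AneuploidyModel(euploid_profiles, sim.arm_map, u.AneuploidyConfig(seed=1)).fit()


@pytest.fixture(scope="session")
def early_cohort(sim):
    return sim.simulate_cohort("early_detection")


@pytest.fixture(scope="session")
def early_results(sim, caller, aneuploidy_fit, early_cohort):
    """Combined per-patient results for the early-detection cohort."""
    calls, flags = caller.call(early_cohort.mutation_obs)
    scores = aneuploidy_fit.score_profiles(early_cohort.locus_counts)
    truth = early_cohort.truth.set_index("patient_id")
    combined = u.combine_cohort(flags, scores, truth["cytology"])
    return {"calls": calls, "flags": flags, "scores": scores,
            "combined": combined, "truth": truth}
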