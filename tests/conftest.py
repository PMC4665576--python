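"""Shared fixtures: the CAD worked example, built from its printed counts."""

import numpy as np
import pytest

import facpv

# MDCTA vs conventional angiography, 291 patients: 2x2 cell counts.
CAD_COUNTS = dict(tp=140, fp=13, fn=24, tn=114)

# Pre-test probability of coronary artery disease by presenting symptom,
# as diseased/total counts from prior studies.
CAD_PREVALENCE = [
    ("nonanginal", 146, 913),
    ("atypical", 963, 1931),
    ("typical", 1874, 2108),
]


@pytest.fixture(scope="session")
def cad_table():
    return facpv.TestResultsTable.from_counts(**CAD_COUNTS, label="MDCTA")


@pytest.fixture(scope="session")
def cad_accuracy(cad_table):
    return facpv.estimate_accuracy(cad_table)


@pytest.fixture(scope="session")
def cad_prevalence():
    return facpv.read_prevalence(CAD_PREVALENCE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20130315)
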