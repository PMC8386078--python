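"""Shared fixtures: one default-scale simulated study per session, plus
the derived tables several test modules reuse."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromshift import difftest, motifs, peaks
from chromshift.simulate import SimConfig, simulate_study

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study():
    return simulate_study(SimConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def dar_table(study):
    factors = difftest.tmm_factors(study.counts)
    table = difftest.moderated_test(
        study.counts, factors, study.groups, "ctrl", "trt",
        feature_ids=[iv.name for iv in study.regions],
    )
    return difftest.classify_features(table)


@pytest.fixture(scope="session")
def refined_summits(study):
    summits = [s for lst in study.replicate_summits.values() for s in lst]
    kept, _ = peaks.refine_summits(study.regions, summits, 500)
    return kept


@pytest.fixture(scope="session")
def ctcf_hits(study):
    return motifs.scan_pwm(study.genome, study.pwms[0], 1e-4)


@pytest.fixture(scope="session")
def partner_hits(study):
    return motifs.scan_pwm(study.genome, study.pwms[1], 1e-4)


@pytest.fixture(scope="session")
def decoy_hits(study):
    return motifs.scan_pwm(study.genome, study.pwms[2], 1e-4)


@pytest.fixture(scope="session")
def class_map(dar_table):
    return dict(zip(dar_table["feature"], dar_table["class"]))


@pytest.fixture(scope="session")
def regions_by_class(study, class_map):
    out = {}
    for cls in ("decreased", "increased", "control"):
        out[cls] = [iv for iv in study.regions if class_map[iv.name] == cls]
    return out


@pytest.fixture(scope="session")
def summits_by_class(refined_summits, class_map):
    out = {}
    for cls in ("decreased", "increased", "control"):
        out[cls] = [(r, s) for r, s in refined_summits
                    if class_map[r.name] == cls]
    return out
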