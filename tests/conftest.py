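"""Shared fixtures: small hand-audited catalogs and session-scoped cohorts.

Everything is generated programmatically; the expensive synthetic-cohort
pipelines are session-scoped so classifier- and TOO-level tests share one
simulation each.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfrefrag.catalog import RepeatRegion, make_region
from cfrefrag.fragments import Fragment
from cfrefrag.pipeline import extract_features, too_matrix
from cfrefrag.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def filter_fixture():
    """12 hand-placed regions exercising every cfRE filter step.

    Hand-derived audit: step i removes the Unknown region, step ii the
    blacklisted one, step iii the never-covered L1, step iv the region absent
    from the reference sample, and step v the single-member MIR family
    (min_family_instances=2); exactly 7 regions survive.
    """
    mk = make_region
    regions = [
        mk("chr1", 1000, 1280, "+", "AluY", "SINE", "Alu"),          # survives
        mk("chr1", 2000, 2280, "+", "AluSx", "SINE", "Alu"),         # survives
        mk("chr1", 3000, 3280, "+", "AluJb", "SINE", "Alu"),         # survives
        mk("chr1", 4000, 4020, "+", "(AT)10", "Simple_repeat", "Simple_repeat"),
        mk("chr1", 5000, 5021, "+", "(CAG)7", "Simple_repeat", "Simple_repeat"),
        mk("chr1", 6000, 6600, "+", "L1PA2", "LINE", "L1"),          # survives
        mk("chr1", 7000, 7600, "+", "L1MB6", "LINE", "L1"),          # survives
        mk("chr1", 8000, 8200, "+", "UnNamed", "Unknown", "Unknown"),  # step i
        mk("chr1", 9000, 9280, "+", "AluYk2", "SINE", "Alu"),        # step ii
        mk("chr1", 10000, 10600, "+", "L1dead", "LINE", "L1"),       # step iii
        mk("chr1", 11000, 11280, "+", "AluYb8", "SINE", "Alu"),      # step iv
        mk("chr1", 12000, 12200, "+", "MIR3", "SINE", "MIR"),        # step v
    ]
    blacklist = [("chr1", 8950, 9330)]
    covered_everywhere = np.ones(len(regions), dtype=np.int64)
    coverage = {}
    for s in range(5):
        counts = covered_everywhere.copy()
        counts[9] = 0  # the dead L1 is covered nowhere
        coverage[f"S{s}"] = counts
    ref = covered_everywhere.copy()
    ref[9] = 0
    ref[10] = 0  # absent only from the reference plasma
    coverage["REF"] = ref
    expected_audit = {
        "i_unclassified": 1,
        "ii_excluded": 1,
        "iii_zero_coverage": 1,
        "iv_reference_zero": 1,
        "v_rare_family": 1,
    }
    surviving_names = {"AluY", "AluSx", "AluJb", "(AT)10", "(CAG)7", "L1PA2", "L1MB6"}
    return {
        "regions": regions,
        "blacklist": blacklist,
        "coverage": coverage,
        "expected_audit": expected_audit,
        "surviving_names": surviving_names,
        "min_family_instances": 2,
    }


@pytest.fixture(scope="session")
def qc_fixture():
    """Six fragments: one per drop reason plus two clean ones."""
    mk = Fragment
    frags = [
        mk("chr1", 100, 260, name="clean1", mapq=60),
        mk("chr1", 300, 470, name="dup", mapq=60, is_duplicate=True),
        mk("chr1", 500, 650, name="supp", mapq=60, is_supplementary=True),
        mk("chr1", 700, 860, name="lowmapq", mapq=10),
        mk("chr1", 900, 1060, name="single", mapq=60, both_ends_mapped=False),
        mk("chr1", 1100, 1270, name="clean2", mapq=30),
    ]
    return frags


@pytest.fixture(scope="session")
def cohort_cfg():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(cohort_cfg):
    return simulate_cohort(cohort_cfg)


@pytest.fixture(scope="session")
def cohort_features(cohort):
    return extract_features(cohort, seed=1)


@pytest.fixture(scope="session")
def too_cohort():
    return simulate_cohort(SimulationConfig(seed=2, n_healthy=5, n_cancer=45))


@pytest.fixture(scope="session")
def too_data(too_cohort):
    cf = extract_features(too_cohort, seed=2)
    X, y, region_sets = too_matrix(too_cohort, cf)
    return {"cf": cf, "X": X, "y": y, "region_sets": region_sets}
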