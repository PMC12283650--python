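"""End-to-end orchestration on in-memory cohorts.

Chains the stages together — QC, cfRE filtering, per-sample features, STR
sub-group scores and weights, FE, model matrices — so the classifier and
tissue-of-origin evaluations can be run from a single simulated (or loaded)
cohort.  Used by the CLI, the test-suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, expansion, too
from .catalog import (
    CfreCatalog,
    build_str_subgroups,
    filter_cfre,
    region_fragment_counts,
)
from .features import SampleFeatures, compute_sample_features
from .fragments import Fragment, QcPolicy
from .simulate import Cohort, SimulationConfig, simulate_cohort
from .too import PeakSet

__all__ = ["CohortFeatures", "build_catalog", "extract_features", "run_pipeline"]

#: FC median read cap per family (deterministic by fragment name)
FC_MAX_READS = 200


@dataclass
class CohortFeatures:
    catalog: CfreCatalog
    sample_features: dict[str, SampleFeatures]
    fe_scores: dict[str, float]
    fe_weights: expansion.SubgroupWeights
    score_matrix: pd.DataFrame  # per-sample STR sub-group scores
    coverage: pd.DataFrame      # per-region fragment counts (regions x samples)
    labels: dict[str, str]
    cancer_types: dict[str, str | None]
    X: pd.DataFrame = field(default_factory=pd.DataFrame)
    y: pd.Series = field(default_factory=pd.Series)


def qc_filter(fragments: Sequence[Fragment], policy: QcPolicy | None = None):
    policy = policy or QcPolicy()
    kept, dropped = [], {}
    for frag in fragments:
        reason = policy.failure_reason(frag)
        if reason is None:
            kept.append(frag)
        else:
            dropped[reason] = dropped.get(reason, 0) + 1
    return kept, dropped


def build_catalog(cohort: Cohort, qualified: Mapping[str, list[Fragment]],
                  reference: list[Fragment]) -> CfreCatalog:
    """Five-step cfRE filter on the cohort's annotation, then STR sub-groups."""
    regions = cohort.genome.regions
    coverage = {
        sid: region_fragment_counts(regions, frags)
        for sid, frags in qualified.items()
    }
    coverage["REF"] = region_fragment_counts(regions, reference)
    catalog = filter_cfre(
        regions,
        coverage,
        reference_sample="REF",
        exclusion=cohort.genome.blacklist,
        min_family_instances=cohort.config.min_family_instances,
    )
    build_str_subgroups(catalog)
    return catalog


def extract_features(
    cohort: Cohort,
    *,
    seed: int = 0,
    fc_max_reads: int | None = FC_MAX_READS,
) -> CohortFeatures:
    """QC, catalog filtering and per-sample feature extraction + FE weights."""
    qualified = {rec.sample_id: qc_filter(rec.fragments)[0] for rec in cohort.samples}
    reference, _ = qc_filter(cohort.reference.fragments)
    catalog = build_catalog(cohort, qualified, reference)

    sample_features: dict[str, SampleFeatures] = {}
    sub_rows: dict[str, dict] = {}
    for rec in cohort.samples:
        sf = compute_sample_features(
            qualified[rec.sample_id], catalog, sample_id=rec.sample_id,
            fc_max_reads=fc_max_reads,
        )
        sample_features[rec.sample_id] = sf
        scores = expansion.subgroup_scores(sf.observations, catalog.subgroups)
        sub_rows[rec.sample_id] = {
            k: (np.nan if v is None else v) for k, v in scores.items()
        }
    score_matrix = pd.DataFrame.from_dict(sub_rows, orient="index")

    labels = {rec.sample_id: rec.label for rec in cohort.samples}
    types = {rec.sample_id: rec.cancer_type for rec in cohort.samples}
    weights = expansion.fit_weights(
        score_matrix, [labels[s] for s in score_matrix.index], seed=seed
    )
    fe = {
        sid: expansion.fe_score(
            {k: (None if pd.isna(v) else v) for k, v in row.items()}, weights
        )
        for sid, row in score_matrix.iterrows()
    }

    coverage = pd.DataFrame(
        {
            sid: region_fragment_counts(catalog.regions, frags)
            for sid, frags in qualified.items()
        }
    )
    cf = CohortFeatures(
        catalog=catalog,
        sample_features=sample_features,
        fe_scores=fe,
        fe_weights=weights,
        score_matrix=score_matrix,
        coverage=coverage,
        labels=labels,
        cancer_types=types,
    )
    cf.X = classify.feature_table(
        [sample_features[rec.sample_id] for rec in cohort.samples], fe
    )
    cf.y = pd.Series(
        [1 if labels[s] == "cancer" else 0 for s in cf.X.index],
        index=cf.X.index, name="label",
    )
    return cf


def run_pipeline(config: SimulationConfig | None = None, *, seed: int = 0):
    """Simulate a cohort and extract everything downstream models need."""
    if config is None:
        config = SimulationConfig(seed=seed)
    cohort = simulate_cohort(config)
    return cohort, extract_features(cohort, seed=seed)


def too_matrix(
    cohort: Cohort,
    cf: CohortFeatures,
    *,
    include_fe: bool = True,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series, dict[str, too.TooRegionSet]]:
    """Recover type-specific regulatory regions and build the TOO matrix."""
    peaksets_by_type: dict[str, list[PeakSet]] = {}
    for (ctype, mark, chip), intervals in cohort.peaks.items():
        peaksets_by_type.setdefault(ctype, []).append(
            PeakSet(ctype, mark, chip, list(intervals))
        )
    candidates = {
        ctype: too.consensus_regions(psets, cf.catalog)
        for ctype, psets in peaksets_by_type.items()
    }
    cancer_ids = [s for s, lbl in cf.labels.items() if lbl == "cancer"]
    sample_types = {s: cf.cancer_types[s] for s in cancer_ids}
    region_sets = too.cancer_specific_regions(
        candidates, cf.coverage[cancer_ids], sample_types, alpha=alpha
    )
    qualified = {
        rec.sample_id: qc_filter(rec.fragments)[0]
        for rec in cohort.samples
        if rec.sample_id in sample_types
    }
    rows = {}
    for sid in cancer_ids:
        row, _flagged = too.too_features(
            qualified[sid], region_sets, cf.catalog,
            sample_id=sid, include_fe=include_fe,
        )
        rows[sid] = row
    X = pd.DataFrame.from_dict(rows, orient="index")
    y = pd.Series({sid: sample_types[sid] for sid in X.index}, name="cancer_type")
    return X, y, region_sets
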