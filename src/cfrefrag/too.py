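"""Tissue-of-origin prediction from cancer-type-specific regulatory repeats.

Candidate regulatory cfRE regions for a cancer type are Alu/STR catalog
regions supported by histone-mark ChIP evidence: a mark supports a region
when more than half of that mark's ChIP samples carry an overlapping peak,
and a region qualifies when at least two of H3K27ac / H3K4me1 / H3K4me3
support it.  Type specificity is then tested per region with Fisher's exact
test on a one-vs-rest 2x2 table of samples with vs without fragment
coverage; a region is assigned to the type when the sample odds ratio
exceeds 1 and the BH-adjusted two-sided p-value is below 0.05.

Per-sample TOO features reuse the FR/FL/FD/FC (and optionally FE)
operators restricted to each type's region set, and a multiclass model
(random forest by default) is evaluated with out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .catalog import CfreCatalog, StrLocus, build_str_subgroups
from .expansion import fe_score, subgroup_scores
from .features import compute_sample_features
from .fragments import Fragment

__all__ = [
    "PeakSet",
    "TooRegion",
    "TooRegionSet",
    "consensus_regions",
    "odds_ratio",
    "fisher_exact_p",
    "cancer_specific_regions",
    "too_features",
    "train_too",
    "too_permutation_null",
]


@dataclass
class PeakSet:
    cancer_type: str
    mark: str
    chip_sample: str
    intervals: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"invalid peak interval {chrom}:{start}-{end}")


@dataclass
class TooRegion:
    region_index: int
    marks_present: int
    odds_ratio: float = float("nan")
    p: float = float("nan")
    p_adj: float = float("nan")


@dataclass
class TooRegionSet:
    cancer_type: str
    regions: list[TooRegion] = field(default_factory=list)

    @property
    def region_indices(self) -> list[int]:
        return [r.region_index for r in self.regions]


def _overlaps(interval: tuple[str, int, int], region) -> bool:
    chrom, start, end = interval
    return chrom == region.chrom and start < region.end and end > region.start


def consensus_regions(
    peaksets: Sequence[PeakSet], catalog: CfreCatalog
) -> list[TooRegion]:
    """Candidate regions supported by >=2 marks, each in >half its ChIP samples."""
    by_mark: dict[str, list[PeakSet]] = {}
    for ps in peaksets:
        by_mark.setdefault(ps.mark, []).append(ps)
    candidates: list[TooRegion] = []
    for idx, region in enumerate(catalog.regions):
        if region.family_key not in {"Alu", "Simple_repeat"}:
            continue
        marks_present = 0
        for mark, sets in by_mark.items():
            if not sets:
                continue
            supported = sum(
                any(_overlaps(iv, region) for iv in ps.intervals) for ps in sets
            )
            if supported > len(sets) / 2:
                marks_present += 1
        if marks_present >= 2:
            candidates.append(TooRegion(idx, marks_present))
    return candidates


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample (cross-product) odds ratio with Haldane 0.5 correction on zeros."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_exact_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value of the 2x2 table [[a, b], [c, d]]."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def cancer_specific_regions(
    candidates_by_type: Mapping[str, Sequence[TooRegion]],
    coverage: pd.DataFrame,
    sample_types: Mapping[str, str],
    *,
    alpha: float = 0.05,
) -> dict[str, TooRegionSet]:
    """Assign candidate regions to cancer types by Fisher's exact test.

    ``coverage`` holds per-sample fragment counts for catalog regions (rows =
    region indices, columns = cancer-sample ids).  For each candidate region
    of type t the 2x2 table counts samples of t with/without >=1 fragment
    against samples of all other types; the region is kept iff OR > 1 and
    BH-adjusted p < alpha.
    """
    types = sorted(set(sample_types.values()))
    if len(types) < 2:
        raise ValueError("need >=2 cancer types")
    for t in types:
        if sum(1 for v in sample_types.values() if v == t) < 3:
            raise ValueError(f"cancer type {t!r} has fewer than 3 samples")
    covered = coverage > 0
    out: dict[str, TooRegionSet] = {}
    for ctype, candidates in candidates_by_type.items():
        in_type = [s for s in coverage.columns if sample_types[s] == ctype]
        other = [s for s in coverage.columns if sample_types[s] != ctype]
        tested: list[TooRegion] = []
        for cand in candidates:
            row = covered.loc[cand.region_index]
            a = int(row[in_type].sum())
            b = len(in_type) - a
            c = int(row[other].sum())
            d = len(other) - c
            cand.odds_ratio = odds_ratio(a, b, c, d)
            cand.p = fisher_exact_p(a, b, c, d)
            tested.append(cand)
        if tested:
            padj = stats.false_discovery_control([c.p for c in tested])
            for cand, q in zip(tested, padj):
                cand.p_adj = float(q)
        out[ctype] = TooRegionSet(
            ctype,
            [c for c in tested if c.odds_ratio > 1.0 and c.p_adj < alpha],
        )
    return out


def _sub_catalog(catalog: CfreCatalog, indices: Sequence[int]) -> CfreCatalog:
    sub = CfreCatalog([catalog.regions[i] for i in indices])
    if any(isinstance(r, StrLocus) for r in sub.regions):
        build_str_subgroups(sub)
    return sub


def too_features(
    fragments: Sequence[Fragment],
    region_sets: Mapping[str, TooRegionSet],
    catalog: CfreCatalog,
    *,
    sample_id: str = "",
    include_fe: bool = True,
    fe_weights: Mapping | None = None,
    fc_max_reads: int | None = 200,
) -> tuple[dict[str, float], list[str]]:
    """Per-type TOO score vector for one sample.

    Returns (feature dict keyed '<type>:<SCORE>', list of types whose region
    set was empty and were therefore flagged).  FE per type uses uniform
    sub-group weights unless ``fe_weights`` provides them.
    """
    row: dict[str, float] = {}
    flagged: list[str] = []
    for ctype in sorted(region_sets):
        indices = region_sets[ctype].region_indices
        if not indices:
            flagged.append(ctype)
            continue
        sub = _sub_catalog(catalog, indices)
        sf = compute_sample_features(
            fragments, sub, sample_id=sample_id,
            collect_observations=include_fe, fc_max_reads=fc_max_reads,
        )
        merged = {"fr": 0.0, "fl": [], "fd": [], "fc": []}
        for fam_scores in sf.families.values():
            merged["fr"] += fam_scores.fr
            if fam_scores.fl is not None:
                merged["fl"].append(fam_scores.fl)
            merged["fd"].append(fam_scores.fd)
            if fam_scores.fc is not None:
                merged["fc"].append(fam_scores.fc)
        row[f"{ctype}:FR"] = merged["fr"]
        row[f"{ctype}:FL"] = float(np.mean(merged["fl"])) if merged["fl"] else np.nan
        row[f"{ctype}:FD"] = float(np.mean(merged["fd"])) if merged["fd"] else np.nan
        row[f"{ctype}:FC"] = float(np.mean(merged["fc"])) if merged["fc"] else np.nan
        if include_fe:
            if sub.subgroups:
                scores = subgroup_scores(sf.observations, sub.subgroups)
                if fe_weights is not None:
                    row[f"{ctype}:FE"] = fe_score(scores, fe_weights)
                else:
                    vals = [s for s in scores.values() if s is not None]
                    row[f"{ctype}:FE"] = float(np.mean(vals)) if vals else 0.0
            else:
                row[f"{ctype}:FE"] = 0.0
    if len(flagged) == len(region_sets):
        raise ValueError(f"sample {sample_id!r}: all TOO region sets empty")
    return row, flagged


def train_too(
    X: pd.DataFrame,
    types: pd.Series,
    *,
    algorithm: str = "random-forest",
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 300,
) -> tuple[pd.Series, float, pd.DataFrame, object]:
    """Multiclass TOO model with out-of-fold predictions.

    Returns (out-of-fold predictions, overall accuracy, confusion table with
    true types as rows, fitted model).  Types with fewer samples than folds
    trigger a reduced stratified fold count.
    """
    y = types.to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need >=2 cancer types")
    min_count = min(int(np.sum(y == c)) for c in classes)
    eff_folds = min(folds, min_count)
    if eff_folds < folds:
        import warnings

        warnings.warn(f"reducing folds to {eff_folds} (smallest class)")

    def make():
        if algorithm == "random-forest":
            model = RandomForestClassifier(n_estimators=n_trees,
                                           random_state=seed, n_jobs=1)
        elif algorithm == "multinomial-logistic":
            model = LogisticRegression(max_iter=5000, random_state=seed)
        else:
            raise ValueError(f"unknown TOO algorithm {algorithm!r}")
        return Pipeline(
            [
                ("impute", SimpleImputer(strategy="median")),
                ("scale", StandardScaler()),
                ("model", model),
            ]
        )

    Xv = X.to_numpy(dtype=float)
    skf = StratifiedKFold(eff_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(Xv, y):
        pipe = make()
        pipe.fit(Xv[train_idx], y[train_idx])
        pred[test_idx] = pipe.predict(Xv[test_idx])
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=classes, columns=classes, fill_value=0)
    accuracy = float(np.trace(confusion.to_numpy()) / confusion.to_numpy().sum())
    final = make().fit(Xv, y)
    return pd.Series(pred, index=X.index, name="predicted"), accuracy, confusion, final


def too_permutation_null(
    X: pd.DataFrame,
    types: pd.Series,
    *,
    n_permutations: int = 100,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> np.ndarray:
    """Out-of-fold accuracies under label permutation."""
    rng = np.random.default_rng(seed)
    accs = np.empty(n_permutations)
    for p in range(n_permutations):
        perm = pd.Series(rng.permutation(types.to_numpy()), index=types.index)
        _, acc, _, _ = train_too(
            X, perm, folds=folds, seed=seed + p, n_trees=n_trees
        )
        accs[p] = acc
    return accs
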