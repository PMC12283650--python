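"""STR expansion detection and the weighted fragment-expansion (FE) score.

A read witnesses an *expansion* at an STR locus when the longest tandem run
of the locus motif in its sequence exceeds the reference unit count ``n2``.
Unit counting works on the read sequence itself (longest exact run of any
cyclic rotation of the motif), so it behaves identically for BED+FASTA and
BAM inputs; reads overlapping a locus by less than one full unit cannot
witness a count and are skipped.

Per STR sub-group the expansion score is the pooled ratio
``score_g = sum(N_ETR) / sum(N)`` over member loci, where ``N`` counts
evaluated reads and ``N_ETR`` those carrying more units than the reference.
Sub-group weights are impurity importances of a random-forest classifier
averaged over stratified cross-validation folds and normalised to sum to 1;
the per-sample FE score is the weight-averaged sub-group score
``FE = sum_g W_g * score_g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .catalog import CfreCatalog, StrLocus
from .fragments import Fragment

__all__ = [
    "ExpansionObservation",
    "SubgroupWeights",
    "count_units",
    "observe_locus",
    "subgroup_scores",
    "fit_weights",
    "fe_score",
]


@dataclass
class ExpansionObservation:
    """Read tally at one STR locus."""

    locus_index: int
    N: int = 0
    N_ETR: int = 0
    N_contracted: int = 0  # reads spanning the locus with fewer units; not scored

    def __post_init__(self) -> None:
        if not 0 <= self.N_ETR <= self.N:
            raise ValueError("require 0 <= N_ETR <= N")


@dataclass
class SubgroupWeights:
    weights: dict[tuple[int, str], float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if self.weights and abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total})")


def _longest_run_units(segment: str, motif: str) -> int:
    """Longest run of consecutive motif copies (any cyclic rotation), in units."""
    n1 = len(motif)
    L = len(segment)
    if L < n1:
        return 0
    best = 0
    rotations = {motif[i:] + motif[:i] for i in range(n1)}
    for rot in rotations:
        # run[i] = number of consecutive rot-copies starting at i
        run = [0] * (L + n1)
        for i in range(L - n1, -1, -1):
            if segment[i : i + n1] == rot:
                run[i] = run[i + n1] + 1
        m = max(run)
        if m > best:
            best = m
    return best


def count_units(fragment: Fragment, locus: StrLocus) -> int | None:
    """Observed motif unit count of ``fragment`` at ``locus``.

    The scan is restricted to the part of the read sequence facing the locus
    padded by one unit on each side; insertions within the locus lengthen the
    sequence relative to the genomic span and are absorbed by anchoring the
    suffix cut from the read's end.  Returns ``None`` when the read carries
    no sequence or overlaps the locus by less than one full unit.
    """
    seq = fragment.sequence
    if not seq:
        return None
    n1 = locus.n1
    overlap = min(fragment.end, locus.end) - max(fragment.start, locus.start)
    if overlap < n1:
        return None
    lo = max(0, (locus.start - n1) - fragment.start)
    hi = len(seq) - max(0, fragment.end - (locus.end + n1))
    if hi <= lo:
        return None
    return _longest_run_units(seq[lo:hi], locus.motif)


def observe_locus(
    fragments: Sequence[Fragment], locus: StrLocus, locus_index: int = 0
) -> ExpansionObservation:
    """Tally evaluated/expanded/contracted reads at one locus."""
    obs = ExpansionObservation(locus_index)
    for frag in fragments:
        units = count_units(frag, locus)
        if units is None or units == 0:
            continue
        obs.N += 1
        if units > locus.n2:
            obs.N_ETR += 1
        elif (
            units < locus.n2
            and frag.start <= locus.start
            and frag.end >= locus.end
        ):
            obs.N_contracted += 1
    return obs


def subgroup_scores(
    observations: Mapping[int, ExpansionObservation],
    subgroups: Mapping[tuple[int, str], Sequence[int]],
) -> dict[tuple[int, str], float | None]:
    """Pooled expansion score per sub-group: sum(N_ETR)/sum(N), None if N=0."""
    scores: dict[tuple[int, str], float | None] = {}
    for key, loci in subgroups.items():
        n = sum(observations[i].N for i in loci if i in observations)
        n_etr = sum(observations[i].N_ETR for i in loci if i in observations)
        scores[key] = (n_etr / n) if n > 0 else None
    return scores


def fit_weights(
    score_matrix: pd.DataFrame,
    labels: Sequence[str],
    *,
    n_folds: int = 5,
    seed: int = 0,
    n_trees: int = 500,
) -> SubgroupWeights:
    """Sub-group weights from RF variable importance over CV folds.

    ``score_matrix`` holds per-sample sub-group scores (missing scores as
    NaN; treated as 0).  Impurity importances are averaged over the training
    side of ``n_folds`` stratified folds, floored at 0 and normalised to
    sum to 1.
    """
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("fit_weights requires at least two classes")
    X = score_matrix.fillna(0.0).to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    importances = np.zeros(X.shape[1])
    for fold, (train_idx, _) in enumerate(skf.split(X, y)):
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed + fold, n_jobs=1
        )
        rf.fit(X[train_idx], y[train_idx])
        importances += rf.feature_importances_
    importances = np.clip(importances / n_folds, 0.0, None)
    if importances.sum() <= 0:
        importances = np.ones_like(importances)
    importances /= importances.sum()
    weights = {col: float(w) for col, w in zip(score_matrix.columns, importances)}
    return SubgroupWeights(
        weights,
        provenance={"n_folds": n_folds, "seed": seed, "n_trees": n_trees,
                    "importance": "impurity"},
    )


def fe_score(
    scores: Mapping[tuple[int, str], float | None],
    weights: SubgroupWeights | Mapping[tuple[int, str], float],
) -> float:
    """Weighted sum of sub-group expansion scores; missing scores count as 0."""
    w = weights.weights if isinstance(weights, SubgroupWeights) else weights
    return float(
        sum(w[key] * score for key, score in scores.items()
            if score is not None and key in w)
    )
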