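"""Cancer-vs-healthy modelling on the multimodal cfRE feature matrix.

The feature matrix concatenates FR/FL/FD/FC per whitelisted repeat family
(Alu and Simple_repeat by default) with the scalar FE score.  Models are
evaluated with out-of-fold scores from stratified cross-validation so the
reported AUC is honest; missing FL values are median-imputed and columns
z-scored inside each training fold only.  The operating threshold maximises
the Youden index (sensitivity + specificity - 1), and confusion-matrix
metrics follow the usual definitions: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), PPV TP/(TP+FP), NPV TN/(TN+FN), accuracy (TP+TN)/total.

Sequencing-depth robustness is probed by per-fragment Bernoulli downsampling
(equivalent in expectation to read-level resampling) and Spearman
correlation of the feature vector at each fraction against full depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .expansion import subgroup_scores
from .features import SampleFeatures
from .fragments import Fragment

__all__ = [
    "ConfusionCounts",
    "ModelResult",
    "DEFAULT_FAMILY_WHITELIST",
    "ALGORITHMS",
    "assemble_matrix",
    "feature_table",
    "train_lasso",
    "train_ensemble",
    "youden_threshold",
    "confusion_at_threshold",
    "classification_metrics",
    "permutation_null_auc",
    "downsample",
    "depth_robustness",
    "differential_regions",
]

DEFAULT_FAMILY_WHITELIST = ("Alu", "Simple_repeat")
ALGORITHMS = (
    "elastic-net",
    "gradient-boosting",
    "knn",
    "lasso-logistic",
    "lda",
    "naive-bayes",
    "random-forest",
    "svm",
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ModelResult:
    algorithm: str
    scores: pd.Series          # out-of-fold scores, higher = more cancer-like
    labels: pd.Series
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    confusion: ConfusionCounts
    metrics: dict[str, float | None]
    cv_scheme: str
    seed: int
    model: object = None


def feature_table(
    sample_features: Sequence[SampleFeatures],
    fe_scores: Mapping[str, float] | None = None,
    family_whitelist: Sequence[str] = DEFAULT_FAMILY_WHITELIST,
) -> pd.DataFrame:
    """Wide per-sample feature matrix: columns '<family>:<SCORE>' (+ 'FE')."""
    rows = {}
    for sf in sample_features:
        row: dict[str, float] = {}
        for fam in family_whitelist:
            scores = sf.families.get(fam)
            if scores is None:
                raise KeyError(f"sample {sf.sample_id}: family {fam!r} missing")
            row[f"{fam}:FR"] = scores.fr
            row[f"{fam}:FL"] = np.nan if scores.fl is None else scores.fl
            row[f"{fam}:FD"] = scores.fd
            row[f"{fam}:FC"] = np.nan if scores.fc is None else scores.fc
        if fe_scores is not None:
            row["FE"] = fe_scores[sf.sample_id]
        rows[sf.sample_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def assemble_matrix(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    *,
    positive: str = "cancer",
    train_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Align features with labels, impute and standardise.

    Missing values are filled with the training-cohort median and columns
    z-scored using training-row statistics only (training rows default to
    all rows).  For honest cross-validation prefer the raw table: the model
    pipelines refit imputation/scaling inside each fold.
    """
    missing = [sid for sid in features.index if sid not in labels]
    if missing:
        raise KeyError(f"samples missing from sheet: {missing}")
    y = pd.Series({sid: labels[sid] for sid in features.index}, name="label")
    train = features.loc[list(train_ids)] if train_ids is not None else features
    med = train.median()
    X = features.fillna(med)
    mu, sd = X.loc[train.index].mean(), X.loc[train.index].std(ddof=0)
    sd = sd.replace(0.0, 1.0)
    X = (X - mu) / sd
    return X, (y == positive).astype(int)


def _make_estimator(name: str, seed: int):
    inner_cv = StratifiedKFold(5, shuffle=True, random_state=seed)
    if name == "lasso-logistic":
        return LogisticRegressionCV(
            Cs=np.logspace(-2, 2, 7), cv=inner_cv, l1_ratios=(1.0,),
            solver="liblinear", scoring="roc_auc", max_iter=2000,
            random_state=seed, use_legacy_attributes=False,
        )
    if name == "elastic-net":
        return LogisticRegression(
            solver="saga", l1_ratio=0.5, C=1.0, max_iter=8000,
            random_state=seed,
        )
    if name == "random-forest":
        return RandomForestClassifier(n_estimators=300, random_state=seed, n_jobs=1)
    if name == "gradient-boosting":
        return GradientBoostingClassifier(random_state=seed)
    if name == "svm":
        return SVC(kernel="rbf", random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "naive-bayes":
        return GaussianNB()
    if name == "lda":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown algorithm {name!r}")


def _pipeline(name: str, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median")),
            ("scale", StandardScaler()),
            ("model", _make_estimator(name, seed)),
        ]
    )


def _oof_scores(
    X: pd.DataFrame, y: np.ndarray, name: str, folds: int, seed: int
) -> np.ndarray:
    """Out-of-fold decision scores from stratified CV."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    Xv = X.to_numpy(dtype=float)
    for train_idx, test_idx in skf.split(Xv, y):
        pipe = _pipeline(name, seed)
        pipe.fit(Xv[train_idx], y[train_idx])
        if hasattr(pipe, "predict_proba"):
            try:
                scores[test_idx] = pipe.predict_proba(Xv[test_idx])[:, 1]
                continue
            except AttributeError:
                pass
        scores[test_idx] = pipe.decision_function(Xv[test_idx])
    return scores


def _bootstrap_auc_ci(
    scores: np.ndarray, y: np.ndarray, seed: int, n_boot: int = 200
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    aucs = []
    idx = np.arange(len(y))
    for _ in range(n_boot):
        b = rng.choice(idx, size=len(idx), replace=True)
        if len(np.unique(y[b])) < 2:
            continue
        aucs.append(roc_auc_score(y[b], scores[b]))
    if not aucs:
        return (float("nan"), float("nan"))
    return (float(np.quantile(aucs, 0.025)), float(np.quantile(aucs, 0.975)))


def _finalize(
    name: str, X: pd.DataFrame, y: pd.Series, scores: np.ndarray,
    folds: int, seed: int,
) -> ModelResult:
    yv = y.to_numpy()
    auc = float(roc_auc_score(yv, scores))
    thr = youden_threshold(scores, yv)
    cc = confusion_at_threshold(scores, yv, thr)
    final = _pipeline(name, seed).fit(X.to_numpy(dtype=float), yv)
    return ModelResult(
        algorithm=name,
        scores=pd.Series(scores, index=X.index, name="score"),
        labels=y,
        auc=auc,
        auc_ci=_bootstrap_auc_ci(scores, yv, seed),
        threshold=thr,
        confusion=cc,
        metrics=classification_metrics(cc),
        cv_scheme=f"stratified-{folds}-fold",
        seed=seed,
        model=final,
    )


def train_lasso(
    X: pd.DataFrame, y: pd.Series, *, folds: int = 10, seed: int = 0
) -> ModelResult:
    """LASSO-penalised logistic regression with honest CV evaluation.

    The penalty strength is re-chosen by inner 5-fold CV inside every outer
    training fold; reported scores are strictly out-of-fold.
    """
    yv = np.asarray(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    scores = _oof_scores(X, yv, "lasso-logistic", folds, seed)
    return _finalize("lasso-logistic", X, y, scores, folds, seed)


def train_ensemble(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    algorithms: Sequence[str] = ALGORITHMS,
    folds: int = 10,
    seed: int = 0,
) -> tuple[ModelResult, dict[str, float]]:
    """Evaluate several algorithms; return the best by CV AUC plus all AUCs.

    Ties are broken by algorithm-name order (lexicographic).
    """
    yv = np.asarray(y)
    results: dict[str, np.ndarray] = {}
    aucs: dict[str, float] = {}
    for name in sorted(algorithms):
        scores = _oof_scores(X, yv, name, folds, seed)
        results[name] = scores
        aucs[name] = float(roc_auc_score(yv, scores))
    best = max(sorted(aucs), key=lambda n: aucs[n])
    return _finalize(best, X, y, results[best], folds, seed), aucs


def youden_threshold(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Threshold maximising Youden's J; ties resolved to the lowest threshold.

    A sample is called positive when its score is >= the threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    best_t, best_j = float(np.min(s)), -np.inf
    for t in np.unique(s):
        pred = s >= t
        tp = int(np.sum(pred & (y == 1)))
        fn = int(np.sum(~pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        fp = int(np.sum(pred & (y == 0)))
        sens = tp / (tp + fn) if tp + fn else 0.0
        spec = tn / (tn + fp) if tn + fp else 0.0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_t = j, float(t)
    return best_t


def confusion_at_threshold(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> ConfusionCounts:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = s >= threshold
    return ConfusionCounts(
        TP=int(np.sum(pred & (y == 1))),
        TN=int(np.sum(~pred & (y == 0))),
        FP=int(np.sum(pred & (y == 0))),
        FN=int(np.sum(~pred & (y == 1))),
    )


def classification_metrics(cc: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, PPV, NPV and accuracy; None on empty denominator."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    return {
        "sensitivity": ratio(cc.TP, cc.TP + cc.FN),
        "specificity": ratio(cc.TN, cc.TN + cc.FP),
        "ppv": ratio(cc.TP, cc.TP + cc.FP),
        "npv": ratio(cc.TN, cc.TN + cc.FN),
        "accuracy": ratio(cc.TP + cc.TN, cc.total),
    }


def permutation_null_auc(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    n_permutations: int = 200,
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold AUCs after label permutation (lightweight lasso model)."""
    rng = np.random.default_rng(seed)
    yv = np.asarray(y)
    Xv = X.to_numpy(dtype=float)
    aucs = np.empty(n_permutations)
    for p in range(n_permutations):
        yp = rng.permutation(yv)
        skf = StratifiedKFold(folds, shuffle=True, random_state=seed + p)
        scores = np.empty(len(yp))
        for train_idx, test_idx in skf.split(Xv, yp):
            pipe = Pipeline(
                [
                    ("impute", SimpleImputer(strategy="median")),
                    ("scale", StandardScaler()),
                    ("model", LogisticRegression(l1_ratio=1.0, C=1.0,
                                                 solver="liblinear")),
                ]
            )
            pipe.fit(Xv[train_idx], yp[train_idx])
            scores[test_idx] = pipe.decision_function(Xv[test_idx])
        aucs[p] = roc_auc_score(yp, scores)
    return aucs


def downsample(
    fragments: Sequence[Fragment], fraction: float, seed: int = 0
) -> list[Fragment]:
    """Keep each fragment independently with probability ``fraction``."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if fraction == 1.0:
        return list(fragments)
    rng = np.random.default_rng(seed)
    mask = rng.random(len(fragments)) < fraction
    return [f for f, keep in zip(fragments, mask) if keep]


def depth_robustness(
    fragments: Sequence[Fragment],
    catalog,
    *,
    fractions: Sequence[float] = (0.1, 0.3, 1.0),
    replicates: int = 10,
    seed: int = 0,
    fc_max_reads: int | None = 200,
) -> pd.DataFrame:
    """Spearman correlation of each feature vector with its full-depth value.

    For every fraction and replicate the sample is Bernoulli-downsampled and
    FR/FL/FD/FC recomputed per family and STR sub-group; the table reports
    the median correlation over replicates (rows = features, columns =
    fractions).
    """
    from .catalog import StrLocus
    from .complexity import linguistic_complexity
    from .features import SHORT_LENGTH_BP, compute_sample_features

    if len(fractions) < 2:
        raise ValueError("need at least two fractions")
    trees = catalog.interval_trees()
    str_n1 = {
        idx: region.n1
        for idx, region in enumerate(catalog.regions)
        if isinstance(region, StrLocus)
    }

    def vectors(frags):
        sf = compute_sample_features(frags, catalog, sample_id="D",
                                     collect_observations=True,
                                     fc_max_reads=fc_max_reads)
        vec: dict[str, dict[str, float]] = {k: {} for k in ("FR", "FL", "FD", "FC")}
        for fam, scores in sf.families.items():
            vec["FR"][fam] = scores.fr
            vec["FL"][fam] = np.nan if scores.fl is None else scores.fl
            vec["FD"][fam] = scores.fd
            vec["FC"][fam] = np.nan if scores.fc is None else scores.fc
        if catalog.subgroups:
            sub = subgroup_scores(sf.observations, catalog.subgroups)
            for key in sub:
                # per-sub-group coverage share refines the FR/FD vectors
                loci = catalog.subgroups[key]
                n = sum(sf.observations[i].N for i in loci if i in sf.observations)
                vec["FR"][f"str{key}"] = n / sf.total_fragments
                vec["FD"][f"str{key}"] = (
                    sum(1 for i in loci if i in sf.observations and
                        sf.observations[i].N > 0) / len(loci)
                )
        # per-unit-length STR groups refine the FC and FL vectors; the
        # family-level vectors alone are too coarse for a stable rank
        # correlation
        buckets: dict[int, list[tuple[str, str]]] = {}
        lengths: dict[int, list[int]] = {}
        for frag in frags:
            tree = trees.get(frag.chrom)
            if tree is None:
                continue
            hit_units = set()
            for iv in tree.overlap(frag.start, frag.end):
                if iv.data in str_n1:
                    hit_units.add(str_n1[iv.data])
            for n1 in hit_units:
                lengths.setdefault(n1, []).append(frag.length)
                if frag.sequence:
                    buckets.setdefault(n1, []).append((frag.name, frag.sequence))
        for n1, seqs in buckets.items():
            seqs = sorted(seqs)
            if fc_max_reads is not None:
                seqs = seqs[:fc_max_reads]
            vec["FC"][f"unit{n1}"] = float(
                np.median([linguistic_complexity(s) for _, s in seqs])
            )
        for n1, lens in lengths.items():
            short = sum(1 for v in lens if v < SHORT_LENGTH_BP)
            long = len(lens) - short
            vec["FL"][f"unit{n1}"] = short / long if long else np.nan
        return vec

    full = vectors(fragments)
    table = pd.DataFrame(index=list(full), columns=list(fractions), dtype=float)
    for fraction in fractions:
        corr: dict[str, list[float]] = {k: [] for k in full}
        for rep in range(replicates):
            sub = downsample(fragments, fraction, seed=seed * 1000 + rep)
            if not sub:
                continue
            down = vectors(sub)
            for feat in full:
                keys = sorted(full[feat])
                a = np.array([full[feat][k] for k in keys], dtype=float)
                b = np.array([down[feat].get(k, np.nan) for k in keys], dtype=float)
                ok = ~(np.isnan(a) | np.isnan(b))
                if ok.sum() < 3:
                    continue
                if np.allclose(a[ok], a[ok][0]) or np.allclose(b[ok], b[ok][0]):
                    corr[feat].append(1.0 if np.allclose(a[ok], b[ok]) else 0.0)
                    continue
                rho = stats.spearmanr(a[ok], b[ok]).statistic
                corr[feat].append(float(rho))
        for feat in full:
            table.loc[feat, fraction] = (
                float(np.median(corr[feat])) if corr[feat] else np.nan
            )
    return table


def differential_regions(
    counts: pd.DataFrame,
    healthy_ids: Sequence[str],
    case_ids: Sequence[str],
    *,
    z_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Regions with |z| > 1 and BH-adjusted rank-sum p < 0.05.

    ``counts`` holds per-region fragment counts (rows = regions, columns =
    samples).  z is the case-mean shift in healthy standard deviations; p
    comes from the two-sided Wilcoxon rank-sum test, Benjamini-Hochberg
    adjusted.  Regions with zero healthy variance are skipped.
    """
    if len(healthy_ids) < 3:
        raise ValueError("need >=3 healthy samples")
    h = counts[list(healthy_ids)].to_numpy(dtype=float)
    c = counts[list(case_ids)].to_numpy(dtype=float)
    sd = h.std(axis=1, ddof=1)
    usable = sd > 0
    z = np.full(len(counts), np.nan)
    z[usable] = (c.mean(axis=1)[usable] - h.mean(axis=1)[usable]) / sd[usable]
    pvals = np.full(len(counts), np.nan)
    for i in np.flatnonzero(usable):
        pvals[i] = stats.ranksums(h[i], c[i]).pvalue
    padj = np.full(len(counts), np.nan)
    padj[usable] = stats.false_discovery_control(pvals[usable])
    out = pd.DataFrame(
        {"z": z, "p": pvals, "p_adj": padj}, index=counts.index
    )
    out["flagged"] = (np.abs(out["z"]) > z_threshold) & (out["p_adj"] < alpha)
    out["flagged"] = out["flagged"].fillna(False)
    return out
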