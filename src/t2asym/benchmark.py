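"""Repeated stratified-holdout benchmark of classifiers and feature filters.

The multivariate stage repeatedly splits the cohort into a stratified
80/20 train/validation partition (default 100 repeats), trains each
method's full pipeline — median imputation, standardisation, feature
selection, classifier — on the training split only, and records the
held-out class predictions and scores. Metrics (accuracy, sensitivity,
specificity, balanced error, ROC AUC) are computed on the pooled
out-of-sample predictions with percentile-bootstrap 95% confidence
intervals over subjects. The progressing group (MCIp) is the positive
class throughout.

Feature-selection filters are pluggable ranking functions (Wilcoxon,
Student t, Kendall tau-b, mRMR, L1-logistic entry order, random-forest
permutation importance, single-tree importance, univariate IDI and NRI).
A bootstrapped forward-stepwise logistic selector stands in for
stage-wise model selection: across B bootstrap resamples of the training
split, features enter a logistic model by likelihood-ratio p < 0.1 and
are kept if selected in at least 30% of the resamples.

How often each feature enters a final trained model across repeats
("selection frequency") identifies the most stable markers per
filter/classifier combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

POSITIVE_CLASS = "MCIp"

# ---------------------------------------------------------------------------
# feature-selection filters: each maps (X, y01, rng) -> full ranking (indices)
# ---------------------------------------------------------------------------


def _safe(values, bad, fill):
    v = np.asarray(values, dtype=float)
    v[~np.isfinite(v)] = fill
    return v


def _rank_by(scores, descending=True):
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s if descending else s, kind="stable")
    return order


def _filter_wilcoxon(X, y, rng):
    p = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p[j] = sps.mannwhitneyu(col[y == 1], col[y == 0],
                                    alternative="two-sided", method="asymptotic").pvalue
    return _rank_by(_safe(p, np.nan, 1.0), descending=False)


def _filter_ttest(X, y, rng):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = sps.ttest_ind(X[y == 1], X[y == 0], axis=0).pvalue
    return _rank_by(_safe(p, np.nan, 1.0), descending=False)


def _kendall_with(X, target):
    taus = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = sps.kendalltau(X[:, j], target, variant="b").correlation
        taus[j] = 0.0 if not np.isfinite(t) else t
    return taus


def _filter_kendall(X, y, rng):
    return _rank_by(np.abs(_kendall_with(X, y)))


def _filter_mrmr(X, y, rng):
    """Greedy mRMR: relevance |tau_b(x, y)| minus mean |tau_b| with selected."""
    n_feat = X.shape[1]
    relevance = np.abs(_kendall_with(X, y))
    selected = [int(np.argmax(relevance))]
    remaining = [j for j in range(n_feat) if j != selected[0]]
    red_cache = {}
    while remaining:
        best, best_score = None, -np.inf
        for j in remaining:
            reds = []
            for s in selected:
                key = (min(j, s), max(j, s))
                if key not in red_cache:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        t = sps.kendalltau(X[:, j], X[:, s], variant="b").correlation
                    red_cache[key] = abs(t) if np.isfinite(t) else 0.0
                reds.append(red_cache[key])
            score = relevance[j] - float(np.mean(reds))
            if score > best_score:
                best, best_score = j, score
        selected.append(best)
        remaining.remove(best)
    return np.asarray(selected)


def _filter_lasso(X, y, rng):
    """Order of entry along an L1-logistic regularisation path."""
    cs = np.logspace(-2.5, 1.5, 25)
    n_feat = X.shape[1]
    entry = np.full(n_feat, len(cs), dtype=float)
    last_coef = np.zeros(n_feat)
    for i, c in enumerate(cs):
        clf = LogisticRegression(penalty="l1", solver="liblinear", C=c, max_iter=500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        nz = np.abs(clf.coef_[0]) > 1e-8
        entry[nz & (entry == len(cs))] = i
        last_coef = clf.coef_[0]
    order = np.lexsort((-np.abs(last_coef), entry))
    return order


def _filter_rf(X, y, rng):
    seed = int(rng.integers(2**31 - 1))
    clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    clf.fit(X, y)
    imp = permutation_importance(clf, X, y, n_repeats=3, random_state=seed)
    return _rank_by(imp.importances_mean)


def _filter_rpart(X, y, rng):
    clf = DecisionTreeClassifier(random_state=int(rng.integers(2**31 - 1)))
    clf.fit(X, y)
    return _rank_by(clf.feature_importances_)


def _univariate_probs(x, y):
    if np.all(x == x[0]):
        return np.full(x.shape[0], y.mean())
    clf = LogisticRegression(max_iter=500)
    clf.fit(x[:, None], y)
    return clf.predict_proba(x[:, None])[:, 1]


def _filter_idi(X, y, rng):
    """Integrated discrimination improvement of a univariate logistic score.

    Baseline is the intercept-only model (constant prevalence), whose
    discrimination slope is 0, so the IDI equals the univariate slope
    mean(p|case) - mean(p|control).
    """
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            scores[j] = -np.inf
            continue
        p = _univariate_probs(X[:, j], y)
        scores[j] = p[y == 1].mean() - p[y == 0].mean()
    return _rank_by(scores)


def _filter_nri(X, y, rng):
    """Net reclassification improvement at threshold 0.5 vs intercept-only."""
    prevalence = y.mean()
    base_pred = int(prevalence > 0.5)
    sens_base = float(base_pred)
    spec_base = float(1 - base_pred)
    scores = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            scores[j] = -np.inf
            continue
        pred = (_univariate_probs(X[:, j], y) > 0.5).astype(int)
        sens = pred[y == 1].mean()
        spec = 1 - pred[y == 0].mean()
        scores[j] = (sens - sens_base) + (spec - spec_base)
    return _rank_by(scores)


FILTERS = {
    "wilcoxon": _filter_wilcoxon,
    "ttest": _filter_ttest,
    "kendall": _filter_kendall,
    "mrmr": _filter_mrmr,
    "lasso": _filter_lasso,
    "rf": _filter_rf,
    "rpart": _filter_rpart,
    "idi": _filter_idi,
    "nri": _filter_nri,
}


def rank_features(name: str, X, y, size: int | None = None, random_state: int = 0):
    """Rank features with a registered filter; return the top ``size`` indices."""
    if name not in FILTERS:
        raise KeyError(f"unknown filter {name!r}; choose from {sorted(FILTERS)}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    order = FILTERS[name](X, y, np.random.default_rng(random_state))
    return order[: size if size is not None else len(order)]


class RankFilterSelector(BaseEstimator, TransformerMixin):
    """Sklearn transformer wrapping a registered ranking filter."""

    def __init__(self, filter_name="wilcoxon", k=10, random_state=0):
        self.filter_name = filter_name
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        k = min(self.k, X.shape[1])
        self.selected_idx_ = np.sort(
            rank_features(self.filter_name, X, y, k, self.random_state)
        )
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_idx_]


class BSWiMSSelector(BaseEstimator, TransformerMixin):
    """Bootstrapped forward-stepwise logistic feature selection.

    For each of ``n_bootstrap`` resamples of the training data, features
    enter a logistic model greedily while the likelihood-ratio test of
    the addition has p < ``entry_p``; features chosen in at least
    ``keep_fraction`` of resamples form the support. Falls back to the
    single best feature if nothing reaches the threshold.
    """

    def __init__(self, n_bootstrap=20, entry_p=0.1, keep_fraction=0.3,
                 max_steps=10, random_state=0):
        self.n_bootstrap = n_bootstrap
        self.entry_p = entry_p
        self.keep_fraction = keep_fraction
        self.max_steps = max_steps
        self.random_state = random_state

    @staticmethod
    def _loglik(X, y):
        """Maximised Bernoulli log-likelihood via Newton-IRLS.

        A tiny ridge (1e-6) keeps the Hessian invertible under perfect
        separation, where the unpenalised likelihood approaches 0 anyway.
        """
        if X.shape[1] == 0:
            p = np.clip(y.mean(), 1e-10, 1 - 1e-10)
            return float(y.sum() * np.log(p) + (len(y) - y.sum()) * np.log(1 - p))
        Z = np.column_stack([np.ones(len(y)), X])
        beta = np.zeros(Z.shape[1])
        for _ in range(25):
            eta = Z @ beta
            mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
            w = np.maximum(mu * (1 - mu), 1e-10)
            grad = Z.T @ (y - mu) - 1e-6 * beta
            hess = (Z * w[:, None]).T @ Z + 1e-6 * np.eye(Z.shape[1])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-8:
                break
        mu = np.clip(1.0 / (1.0 + np.exp(-np.clip(Z @ beta, -30, 30))), 1e-10, 1 - 1e-10)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    def _forward_stepwise(self, X, y):
        selected: list = []
        ll = self._loglik(X[:, []], y)
        while len(selected) < min(self.max_steps, X.shape[1]):
            best, best_ll, best_p = None, None, 1.0
            for j in range(X.shape[1]):
                if j in selected or np.all(X[:, j] == X[0, j]):
                    continue
                ll_new = self._loglik(X[:, selected + [j]], y)
                p = sps.chi2.sf(max(0.0, 2 * (ll_new - ll)), df=1)
                if p < best_p:
                    best, best_ll, best_p = j, ll_new, p
            if best is None or best_p >= self.entry_p:
                break
            selected.append(best)
            ll = best_ll
        return selected

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(self.random_state)
        counts = np.zeros(X.shape[1])
        for _ in range(self.n_bootstrap):
            idx = rng.integers(0, len(y), len(y))
            if len(np.unique(y[idx])) < 2:
                continue
            for j in self._forward_stepwise(X[idx], y[idx]):
                counts[j] += 1
        self.selection_counts_ = counts / self.n_bootstrap
        support = np.flatnonzero(self.selection_counts_ >= self.keep_fraction)
        if support.size == 0:
            support = np.array([int(np.argmax(counts))])
        self.selected_idx_ = np.sort(support)
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.selected_idx_]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


class NearestCentroidScore(BaseEstimator, ClassifierMixin):
    """Nearest-centroid classifier with a continuous score.

    ``metric='euclidean'`` uses plain distances; ``metric='spearman'``
    uses 1 - Spearman rank correlation with each class centroid. The
    decision score is d(negative centroid) - d(positive centroid).
    """

    def __init__(self, metric="euclidean"):
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.centroids_ = {c: X[y == c].mean(axis=0) for c in self.classes_}
        return self

    def _dist(self, X, centroid):
        if self.metric == "euclidean":
            return np.linalg.norm(X - centroid, axis=1)
        if self.metric == "spearman":
            d = np.empty(len(X))
            for i, row in enumerate(X):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho = sps.spearmanr(row, centroid).statistic
                d[i] = 1.0 - (rho if np.isfinite(rho) else 0.0)
            return d
        raise ValueError(f"unknown metric {self.metric!r}")

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self._dist(X, self.centroids_[0]) - self._dist(X, self.centroids_[1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


def classifier_registry(random_state: int = 0) -> dict:
    return {
        "knn": KNeighborsClassifier(n_neighbors=5),
        "logistic": LogisticRegression(penalty=None, max_iter=1000),
        "lasso": LogisticRegression(penalty="l1", solver="liblinear", C=1.0, max_iter=1000),
        "rf": RandomForestClassifier(n_estimators=200, random_state=random_state),
        "rpart": DecisionTreeClassifier(random_state=random_state),
        "svm": SVC(kernel="linear", C=1.0),
        "naive_bayes": GaussianNB(),
        "centroid_euclid": NearestCentroidScore(metric="euclidean"),
        "centroid_spearman": NearestCentroidScore(metric="spearman"),
    }


@dataclass
class MethodSpec:
    """One benchmark arm: optional selector followed by a classifier."""

    name: str
    classifier: str
    selector: str | None = None    # filter name, "bswims", or None
    k: int = 10


def default_methods(filter_k: int = 10) -> list:
    """The standard study design: six method arms plus their majority-vote ensemble."""
    return [
        MethodSpec("BSWiMS", "logistic", "bswims"),
        MethodSpec("KNN", "knn", "bswims"),
        MethodSpec("LASSO", "lasso", None),
        MethodSpec("RF", "rf", None),
        MethodSpec("RPART", "rpart", None),
        MethodSpec("SVM", "svm", "mrmr", filter_k),
    ]


@dataclass
class BenchmarkConfig:
    n_repeats: int = 100
    train_fraction: float = 0.8
    seed: int = 0
    filter_k: int = 10
    n_boot: int = 2000
    include_ensemble: bool = True
    methods: list = None

    def resolved_methods(self) -> list:
        return self.methods if self.methods is not None else default_methods(self.filter_k)


def _build_pipeline(spec: MethodSpec, random_state: int) -> Pipeline:
    steps = [
        ("impute", SimpleImputer(strategy="median")),
        ("scale", StandardScaler()),
    ]
    if spec.selector == "bswims":
        steps.append(("select", BSWiMSSelector(random_state=random_state)))
    elif spec.selector is not None:
        steps.append(
            ("select", RankFilterSelector(spec.selector, spec.k, random_state))
        )
    steps.append(("clf", clone(_CLF_PROTOTYPES[spec.classifier])))
    return Pipeline(steps)


_CLF_PROTOTYPES = classifier_registry(0)


def _scores_of(pipe, X) -> np.ndarray:
    clf = pipe[-1]
    Xt = pipe[:-1].transform(X)
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(Xt)[:, 1]
    return clf.decision_function(Xt)


def _selected_features(pipe, feature_names) -> list:
    """Features entering the final trained model of a fitted pipeline."""
    names = np.asarray(feature_names)
    if "select" in pipe.named_steps:
        names = names[pipe.named_steps["select"].selected_idx_]
    clf = pipe.named_steps["clf"]
    if hasattr(clf, "coef_"):
        nz = np.abs(np.ravel(clf.coef_)) > 1e-8
        if nz.any():
            names = names[nz]
    elif isinstance(clf, DecisionTreeClassifier):
        used = clf.feature_importances_ > 0
        if used.any():
            names = names[used]
    return list(names)


def repeated_holdout(
    X: pd.DataFrame,
    y,
    config: BenchmarkConfig,
):
    """Run every method over shared stratified 80/20 splits.

    Parameters
    ----------
    X : DataFrame
        Subjects x features (NaNs allowed; imputed within training folds).
    y : array-like
        Group labels; ``"MCIp"`` is the positive class.

    Returns
    -------
    (predictions, selections): a DataFrame with one row per held-out
    prediction (method, repeat, subject, y_true, y_pred, score) and a
    dict method -> list (per repeat) of selected feature-name lists.
    """
    y = np.asarray(y)
    y01 = (y == POSITIVE_CLASS).astype(int)
    if y01.sum() == 0 or y01.sum() == len(y01):
        raise ValueError("both classes must be present")
    Xv = X.to_numpy(dtype=float)
    feature_names = list(X.columns)
    subjects = np.asarray(X.index)

    splitter = StratifiedShuffleSplit(
        n_splits=config.n_repeats,
        train_size=config.train_fraction,
        random_state=config.seed,
    )
    splits = list(splitter.split(Xv, y01))

    methods = config.resolved_methods()
    rows, selections = [], {m.name: [] for m in methods}
    if config.include_ensemble:
        selections["ENS"] = []
    for rep, (tr, te) in enumerate(splits):
        member_preds, member_sel = {}, []
        for spec in methods:
            pipe = _build_pipeline(spec, random_state=config.seed * 100003 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pipe.fit(Xv[tr], y01[tr])
                pred = pipe.predict(Xv[te])
                score = _scores_of(pipe, Xv[te])
            sel = _selected_features(pipe, feature_names)
            selections[spec.name].append(sel)
            member_sel.extend(sel)
            member_preds[spec.name] = pred
            for i, t in enumerate(te):
                rows.append((spec.name, rep, subjects[t], y01[t], int(pred[i]), float(score[i])))
        if config.include_ensemble:
            votes = np.vstack([member_preds[m.name] for m in methods])
            frac = votes.mean(axis=0)
            pred = (frac > 0.5).astype(int)
            selections["ENS"].append(sorted(set(member_sel)))
            for i, t in enumerate(te):
                rows.append(("ENS", rep, subjects[t], y01[t], int(pred[i]), float(frac[i])))
    predictions = pd.DataFrame(
        rows, columns=["method", "repeat", "subject", "y_true", "y_pred", "score"]
    )
    return predictions, selections


def _metrics_from_pool(df: pd.DataFrame) -> dict:
    tp = int(((df.y_true == 1) & (df.y_pred == 1)).sum())
    fn = int(((df.y_true == 1) & (df.y_pred == 0)).sum())
    tn = int(((df.y_true == 0) & (df.y_pred == 0)).sum())
    fp = int(((df.y_true == 0) & (df.y_pred == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    out = {
        "accuracy": (tp + tn) / len(df),
        "sensitivity": sens,
        "specificity": spec,
        "balanced_error": 1.0 - (sens + spec) / 2.0,
    }
    if df.y_true.nunique() == 2:
        out["roc_auc"] = roc_auc_score(df.y_true, df.score)
    else:
        out["roc_auc"] = np.nan
    return out


def compute_metrics(
    predictions: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Pooled metrics with percentile-bootstrap CIs, one row per method.

    Predictions from all repeats are pooled into one confusion matrix
    (class decisions at score threshold 0.5 are the pipelines' own
    ``predict``); AUC is the rank statistic over pooled scores. CIs
    resample *subjects* (keeping each subject's pooled predictions
    together) to respect repeat-induced dependence.
    """
    if predictions.empty:
        raise ValueError("no predictions")
    rows = []
    alpha = (1 - ci_level) / 2
    for method, df in predictions.groupby("method", sort=False):
        if df.y_true.nunique() < 2:
            raise ValueError(f"method {method}: single-class prediction pool")
        point = _metrics_from_pool(df)
        subj = df.subject.unique()
        by_subj = {s: g for s, g in df.groupby("subject")}
        rng = np.random.default_rng(seed)
        boots = {k: [] for k in point}
        for _ in range(n_boot):
            take = rng.choice(subj, size=len(subj), replace=True)
            bdf = pd.concat([by_subj[s] for s in take], ignore_index=True)
            if bdf.y_true.nunique() < 2:
                continue
            bm = _metrics_from_pool(bdf)
            for k, v in bm.items():
                boots[k].append(v)
        row = {"method": method}
        for k, v in point.items():
            bs = np.asarray(boots[k], dtype=float)
            bs = bs[np.isfinite(bs)]
            row[k] = v
            row[f"{k}_lo"] = float(np.quantile(bs, alpha)) if bs.size else np.nan
            row[f"{k}_hi"] = float(np.quantile(bs, 1 - alpha)) if bs.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("method")


def selection_frequency(selections: dict, top: int = 6):
    """Per-method feature selection frequencies and top-``top`` lists.

    Returns (frequency DataFrame with columns method, feature, frequency;
    dict method -> ordered top features).
    """
    rows, tops = [], {}
    for method, per_repeat in selections.items():
        n = max(1, len(per_repeat))
        counts: dict = {}
        for sel in per_repeat:
            for f in sel:
                counts[f] = counts.get(f, 0) + 1
        freq = pd.Series(counts, dtype=float).sort_values(ascending=False) / n
        tops[method] = list(freq.index[:top])
        rows += [{"method": method, "feature": f, "frequency": v} for f, v in freq.items()]
    return pd.DataFrame(rows), tops


def selection_grid_methods(filters=None, classifiers=None, k: int = 10) -> list:
    """Filter x classifier grid for the selection-frequency analysis."""
    filters = filters if filters is not None else sorted(FILTERS)
    classifiers = classifiers if classifiers is not None else [
        "knn", "naive_bayes", "centroid_euclid", "centroid_spearman", "rf", "svm",
    ]
    return [
        MethodSpec(f"{f}+{c}", c, f, k) for f in filters for c in classifiers
    ]


def run_experiments(
    table: pd.DataFrame,
    config: BenchmarkConfig,
    imaging_pool: list,
    group_col: str = "group",
) -> dict:
    """The two-experiment design on one feature table.

    Experiment 1 uses the neuropsychological scores only; experiment 2
    adds the pre-screened imaging columns (``imaging_pool``). Both use
    identical splits (same seed), so the imaging increment is paired.

    Returns a dict with per-experiment metric reports, predictions and
    selection frequencies.
    """
    y = table[group_col].to_numpy()
    score_cols = [c for c in table.columns if c.startswith("score_")]
    if not score_cols:
        raise ValueError("table has no neuropsychological score_ columns")
    designs = {
        "neuropsych": score_cols,
        "neuropsych+imaging": score_cols + [c for c in imaging_pool if c in table.columns],
    }
    out = {}
    for name, cols in designs.items():
        preds, sels = repeated_holdout(table[cols], y, config)
        report = compute_metrics(preds, n_boot=config.n_boot, seed=config.seed)
        freq, tops = selection_frequency(sels)
        out[name] = {
            "metrics": report,
            "predictions": preds,
            "selection_frequency": freq,
            "top_features": tops,
        }
    return out
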