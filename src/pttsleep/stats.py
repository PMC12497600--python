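"""Statistical layer: multinomial and logistic regression, iterated
variable selection, a decision-tree cross-check, ROC/AUC, summary-data t
comparisons, and the full diagnostic confusion-matrix metric suite.

Conventions
-----------
The binary outcome codes a sleep disorder (UARS/mild, moderate or severe
OSA) as 1 and normal/primary snoring as 0.  The diagnostic metric tables
follow the convention that the **no-disorder (majority) class is the
positive class** — the printed sensitivities are the no-disorder recall —
so that is the default of :func:`confusion_metrics`, explicit in the API.

The three-level score used by the multinomial model groups the categories
as score 1 = normal/primary snoring, score 2 = UARS/mild OSA, score 3 =
moderate + severe OSA, modelled as log-odds against score 3 (the
reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .synth import MODEL_VARIABLES

#: Covariates of the multinomial score model.
MULTINOMIAL_VARIABLES = ["pttrs", "sex", "mean_nadir", "age_months",
                         "oximetry_score", "weight", "height", "odi4"]

#: The six predictors retained by the study's second selection pass.
SIX_VARIABLES = ["odi3", "mean_spo2", "heart_rate", "ptt_ai", "pttrs",
                 "ptt_duration"]
TWO_VARIABLES = ["odi3", "pttrs"]


class SeparationWarning(UserWarning):
    """Raised when a logistic fit shows (quasi-)complete separation."""


# ---------------------------------------------------------------------------
# Confusion-matrix metric suite
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMetrics:
    """Every field of the diagnostic-performance tables.

    Counts are with respect to the disorder label: ``tn`` = no-disorder
    correctly predicted, ``tp`` = disorder correctly predicted.  Rates are
    computed for ``positive_class`` (default the no-disorder class).
    Undefined ratios (zero denominators) are ``None``.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    positive_class: str
    accuracy: float
    accuracy_ci: tuple[float, float]
    nir: float
    acc_vs_nir_p: float
    kappa: float
    mcnemar_p: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    prevalence: float
    detection_rate: float
    detection_prevalence: float
    balanced_accuracy: float | None

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "tn", "fp", "fn", "tp", "positive_class", "accuracy", "nir",
            "acc_vs_nir_p", "kappa", "mcnemar_p", "sensitivity",
            "specificity", "ppv", "npv", "prevalence", "detection_rate",
            "detection_prevalence", "balanced_accuracy")}
        d["accuracy_ci_low"], d["accuracy_ci_high"] = self.accuracy_ci
        return d


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def confusion_metrics(tn: int, fp: int, fn: int, tp: int,
                      positive_class: str = "no_disorder") -> ConfusionMetrics:
    """Compute the full diagnostic metric suite from confusion counts.

    The accuracy CI is the exact (Clopper-Pearson) binomial interval;
    kappa is chance-corrected agreement; McNemar uses the
    continuity-corrected chi-square on the discordant counts.
    """
    for name, v in dict(tn=tn, fp=fp, fn=fn, tp=tp).items():
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer")
    tn, fp, fn, tp = int(tn), int(fp), int(fn), int(tp)
    total = tn + fp + fn + tp
    if total == 0:
        raise ValueError("empty confusion matrix")
    correct = tn + tp
    accuracy = correct / total
    bt = scipy.stats.binomtest(correct, total)
    ci = bt.proportion_ci(confidence_level=0.95, method="exact")
    neg_total = tn + fp       # reference no-disorder
    pos_total = tp + fn       # reference disorder
    nir = max(neg_total, pos_total) / total
    acc_vs_nir = scipy.stats.binomtest(correct, total, p=nir,
                                       alternative="greater").pvalue
    pe = (neg_total / total) * ((tn + fn) / total) \
        + (pos_total / total) * ((tp + fp) / total)
    kappa = (accuracy - pe) / (1 - pe) if pe < 1 else 1.0
    if fp + fn > 0:
        chi2 = (abs(fp - fn) - 1) ** 2 / (fp + fn)
        mcnemar_p = float(scipy.stats.chi2.sf(chi2, df=1))
    else:
        mcnemar_p = None
    if positive_class == "no_disorder":
        sens = _ratio(tn, tn + fp)
        spec = _ratio(tp, tp + fn)
        ppv = _ratio(tn, tn + fn)
        npv = _ratio(tp, tp + fp)
        prevalence = neg_total / total
        det_rate = tn / total
        det_prev = (tn + fn) / total
    elif positive_class == "disorder":
        sens = _ratio(tp, tp + fn)
        spec = _ratio(tn, tn + fp)
        ppv = _ratio(tp, tp + fp)
        npv = _ratio(tn, tn + fn)
        prevalence = pos_total / total
        det_rate = tp / total
        det_prev = (tp + fp) / total
    else:
        raise ValueError("positive_class must be 'no_disorder' or 'disorder'")
    balanced = (sens + spec) / 2 if sens is not None and spec is not None \
        else None
    return ConfusionMetrics(
        tn=tn, fp=fp, fn=fn, tp=tp, positive_class=positive_class,
        accuracy=accuracy, accuracy_ci=(float(ci.low), float(ci.high)),
        nir=nir, acc_vs_nir_p=float(acc_vs_nir), kappa=float(kappa),
        mcnemar_p=mcnemar_p, sensitivity=sens, specificity=spec, ppv=ppv,
        npv=npv, prevalence=prevalence, detection_rate=det_rate,
        detection_prevalence=det_prev, balanced_accuracy=balanced)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                             positive_class: str = "no_disorder",
                             ) -> ConfusionMetrics:
    """Confusion metrics from binary truth/prediction vectors (disorder=1)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    return confusion_metrics(tn, fp, fn, tp, positive_class)


# ---------------------------------------------------------------------------
# Summary-statistic t comparison
# ---------------------------------------------------------------------------

@dataclass
class GroupTResult:
    difference: float      # mean2 - mean1
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


def group_summary_t(n1: int, mean1: float, sd1: float,
                    n2: int, mean2: float, sd2: float) -> GroupTResult:
    """Pooled-variance two-sample t test from printed (n, mean, SD) triples."""
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if min(sd1, sd2) <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = mean2 - mean1
    t = diff / se
    tcrit = scipy.stats.t.ppf(0.975, df)
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return GroupTResult(difference=float(diff), se=float(se),
                        ci_low=float(diff - tcrit * se),
                        ci_high=float(diff + tcrit * se),
                        t=float(t), df=df, p=float(p))


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray
            ) -> tuple[float, pd.DataFrame]:
    """Trapezoidal AUC over all thresholds plus the curve points.

    Equals the Mann-Whitney pairwise concordance of the scores.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, curve


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A fitted multinomial / logistic / tree model with its report table."""

    kind: str
    variables: list[str]
    table: pd.DataFrame          # coef, se, z, p (per equation if multinomial)
    predict: object              # callable(DataFrame) -> probabilities
    metrics: ConfusionMetrics | None = None
    extra: dict = field(default_factory=dict)

    def coefficients(self) -> pd.Series:
        return self.table["coef"]


def _logit_table(res, names: list[str]) -> pd.DataFrame:
    return pd.DataFrame({
        "coef": np.asarray(res.params, dtype=float),
        "se": np.asarray(res.bse, dtype=float),
        "z": np.asarray(res.tvalues, dtype=float),
        "p": np.asarray(res.pvalues, dtype=float),
    }, index=names)


def fit_logistic(table: pd.DataFrame, variables: list[str],
                 outcome: str = "disorder") -> FittedModel:
    """Maximum-likelihood binary logistic fit on the full dataset.

    Reports coefficient, SE, z and p per variable.  Perfect separation is
    surfaced as a :class:`SeparationWarning` and the fit falls back to a
    lightly regularised solution so diagnostics remain available.
    """
    y = table[outcome].to_numpy(dtype=float)
    X = sm.add_constant(table[list(variables)].astype(float), has_constant="add")
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(disp=0, maxiter=200)
    except Exception as err:  # (quasi-)separation or non-convergence
        warnings.warn(
            f"logistic fit shows separation or failed to converge ({err}); "
            "retrying with a quasi-Newton solver", SeparationWarning,
            stacklevel=2)
        try:
            res = model.fit(disp=0, maxiter=1000, method="bfgs")
        except Exception:
            res = model.fit_regularized(alpha=1e-2, disp=0, maxiter=500)
    if hasattr(res, "mle_retvals") and not res.mle_retvals.get("converged", True):
        warnings.warn("logistic fit did not converge", SeparationWarning,
                      stacklevel=2)
    names = ["intercept"] + list(variables)
    tab = _logit_table(res, names)

    def predict(df: pd.DataFrame) -> np.ndarray:
        Xn = sm.add_constant(df[list(variables)].astype(float),
                             has_constant="add")
        return np.asarray(res.predict(Xn))

    return FittedModel(kind="logistic", variables=list(variables),
                       table=tab, predict=predict, extra={"result": res})


def fit_multinomial(table: pd.DataFrame, outcome: str = "score3",
                    reference: int | str = 3,
                    variables: list[str] | None = None) -> FittedModel:
    """Multinomial logit of a 3-level score against a chosen reference.

    Each non-reference level gets its own log-odds equation
    (level vs reference) over the eight score-model covariates.
    """
    variables = list(variables or MULTINOMIAL_VARIABLES)
    levels = sorted(table[outcome].unique(), key=str)
    if len(levels) != 3:
        raise ValueError(f"outcome must have 3 levels, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference {reference!r} not among levels {levels}")
    order = [reference] + [l for l in levels if l != reference]
    codes = table[outcome].map({l: i for i, l in enumerate(order)}).to_numpy()
    X = sm.add_constant(table[variables].astype(float), has_constant="add")
    model = sm.MNLogit(codes, X)
    try:
        res = model.fit(disp=0, maxiter=500, tol=1e-8)
    except Exception as err:
        warnings.warn(f"multinomial fit failed to converge cleanly ({err})",
                      SeparationWarning, stacklevel=2)
        res = model.fit(disp=0, maxiter=500, method="bfgs")
    if not res.mle_retvals.get("converged", True):
        warnings.warn("multinomial fit did not converge", SeparationWarning,
                      stacklevel=2)
    names = ["intercept"] + variables
    frames = []
    for j, level in enumerate(order[1:]):
        frames.append(pd.DataFrame({
            "coef": res.params.iloc[:, j].to_numpy(),
            "se": res.bse.iloc[:, j].to_numpy(),
            "z": res.tvalues.iloc[:, j].to_numpy(),
            "p": res.pvalues.iloc[:, j].to_numpy(),
            "equation": f"{level} vs {reference}",
        }, index=names))
    tab = pd.concat(frames)

    def predict(df: pd.DataFrame) -> pd.DataFrame:
        Xn = sm.add_constant(df[variables].astype(float), has_constant="add")
        proba = np.asarray(res.predict(Xn))
        return pd.DataFrame(proba, columns=[str(l) for l in order])

    return FittedModel(kind="multinomial", variables=variables, table=tab,
                       predict=predict,
                       extra={"result": res, "levels": order})


@dataclass
class SelectionResult:
    """Nested logistic models from the iterated variable selection."""

    full: FittedModel
    significant: FittedModel | None
    top2: FittedModel | None
    selected: list[str]
    top2_variables: list[str]
    metrics: dict[str, ConfusionMetrics]


def _insample_metrics(model: FittedModel, table: pd.DataFrame,
                      outcome: str = "disorder") -> ConfusionMetrics:
    pred = (model.predict(table) >= 0.5).astype(int)
    return metrics_from_predictions(table[outcome].to_numpy(), pred)


def select_variables(table: pd.DataFrame, alpha: float = 0.05,
                     variables: list[str] | None = None,
                     outcome: str = "disorder") -> SelectionResult:
    """Three-pass logistic variable selection.

    Pass 1 fits all candidate variables and drops those with p > alpha;
    pass 2 refits the survivors; pass 3 keeps the two smallest-p survivors.
    Returns all fitted models with their in-sample confusion metrics.
    """
    variables = list(variables or MODEL_VARIABLES)
    full = fit_logistic(table, variables, outcome)
    pvals = full.table["p"].drop("intercept")
    survivors = [v for v in variables if pvals[v] <= alpha]
    metrics = {"full": _insample_metrics(full, table, outcome)}
    full.metrics = metrics["full"]
    significant = top2 = None
    top2_vars: list[str] = []
    if survivors:
        significant = fit_logistic(table, survivors, outcome)
        metrics["significant"] = _insample_metrics(significant, table, outcome)
        significant.metrics = metrics["significant"]
        p2 = significant.table["p"].drop("intercept").sort_values()
        top2_vars = list(p2.index[:2])
        if len(top2_vars) < 2:
            warnings.warn("fewer than two significant variables; returning "
                          "what exists", UserWarning, stacklevel=2)
        top2 = fit_logistic(table, top2_vars, outcome)
        metrics["top2"] = _insample_metrics(top2, table, outcome)
        top2.metrics = metrics["top2"]
    else:
        warnings.warn("no variable passed the significance screen",
                      UserWarning, stacklevel=2)
    return SelectionResult(full=full, significant=significant, top2=top2,
                           selected=survivors, top2_variables=top2_vars,
                           metrics=metrics)


def fit_tree(table: pd.DataFrame, variables: list[str] | None = None,
             split: float = 0.3, seed: int = 0, max_depth: int = 3,
             outcome: str = "disorder") -> FittedModel:
    """Depth-limited classification tree with a stratified train/test split.

    Metrics are computed on the held-out test split; deterministic for a
    fixed seed.
    """
    variables = list(variables or TWO_VARIABLES)
    X = table[variables].to_numpy(dtype=float)
    y = table[outcome].to_numpy(dtype=int)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=split, random_state=seed, stratify=y)
    if len(np.unique(y_tr)) < 2:
        raise ValueError("training split contains a single class")
    clf = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    clf.fit(X_tr, y_tr)
    mets = metrics_from_predictions(y_te, clf.predict(X_te))
    tab = pd.DataFrame({"coef": clf.feature_importances_,
                        "se": np.nan, "z": np.nan, "p": np.nan},
                       index=variables)

    def predict(df: pd.DataFrame) -> np.ndarray:
        return clf.predict_proba(df[variables].to_numpy(dtype=float))[:, 1]

    return FittedModel(kind="tree", variables=variables, table=tab,
                       predict=predict, metrics=mets,
                       extra={"tree": clf, "test_accuracy": mets.accuracy})
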