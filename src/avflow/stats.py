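"""Cohort-level outcome statistics: group summaries and ROC analysis.

Works on per-fistula tables with the packaged 17-fistula schema
(``patient_id, fistula_type, side, outcome, venous_outflow_ml_min,
outflow_category, fa_diameter_mm, fa_curvature, dv_diameter_mm,
dv_curvature, anastomosis_angle_deg``).  Group summaries use the
population-SD convention (divisor n), which is the convention the packaged
cohort's published summaries follow.  ROC AUCs are Mann-Whitney
concordance probabilities with ties counted one half, cross-checked
internally against the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import hashlib
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

ANATOMICAL_VARIABLES = (
    "fa_diameter_mm",
    "fa_curvature",
    "dv_diameter_mm",
    "dv_curvature",
    "anastomosis_angle_deg",
)

HIGH_FLOW_THRESHOLD = 1000.0  # ml/min, inclusive

_FIXTURE_SHA256 = "567a419b0c3852b450425e1e19208ec0ad8b4f66434ad97c4a4aea08b3e299cc"


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 17-fistula cohort table, values verbatim as published.

    Raises ``ValueError`` on checksum mismatch (a corrupted installation).
    """
    res = importlib.resources.files("avflow.data").joinpath("table2_cohort.csv")
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ValueError(
            f"cohort fixture checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    import io

    return pd.read_csv(io.BytesIO(raw))


def dichotomize_flow(
    cohort: pd.DataFrame, threshold: float = HIGH_FLOW_THRESHOLD
) -> pd.DataFrame:
    """Recompute the High/Low outflow category (High iff flow >= threshold).

    Returns a copy with ``outflow_category`` set; rows with missing outflow
    get a missing category.
    """
    if "venous_outflow_ml_min" not in cohort:
        raise ValueError("cohort table has no venous_outflow_ml_min column")
    out = cohort.copy()
    flow = out["venous_outflow_ml_min"]
    cat = np.where(flow >= threshold, "High", "Low")
    out["outflow_category"] = pd.Series(cat, index=out.index).where(flow.notna())
    return out


def group_summary(
    cohort: pd.DataFrame,
    grouping: str = "outcome",
    variables: tuple[str, ...] = ANATOMICAL_VARIABLES + ("venous_outflow_ml_min",),
) -> pd.DataFrame:
    """Per-group n, mean and population SD (divisor n) for each variable.

    ``grouping`` is a column name (``outcome``, ``outflow_category``,
    ``fistula_type``) or the special value ``rcf`` which splits RCF vs all
    other fistula configurations.
    """
    df = cohort.copy()
    if grouping == "rcf":
        df["_group"] = np.where(df["fistula_type"] == "RCF", "RCF", "non-RCF")
        key = "_group"
    else:
        if grouping not in df:
            raise ValueError(f"unknown grouping column '{grouping}'")
        key = grouping
    rows = []
    for g, sub in df.groupby(key, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        for var in variables:
            x = sub[var].dropna().to_numpy(float)
            rows.append(dict(
                group=g, variable=var, n=len(x),
                mean=float(np.mean(x)), sd=float(np.std(x, ddof=0)),
            ))
    out = pd.DataFrame(rows)
    # group difference column (first group minus second, alphabetical order)
    groups = sorted(out["group"].unique())
    if len(groups) == 2:
        a, b = groups
        diff = (
            out[out.group == a].set_index("variable")["mean"]
            - out[out.group == b].set_index("variable")["mean"]
        )
        out["difference"] = out["variable"].map(diff)
    return out


def vein_minus_artery(cohort: pd.DataFrame) -> pd.Series:
    """Per-fistula draining-vein minus feeding-artery diameter (mm)."""
    return cohort["dv_diameter_mm"] - cohort["fa_diameter_mm"]


@dataclass
class ROCResult:
    """ROC analysis of one predictor (or combined score) against a binary label.

    ``auc`` is orientation-adjusted to be >= 0.5 for single variables, with
    ``orientation`` +1 when larger values predict the positive class and -1
    otherwise.  ``raw_auc`` is the unoriented concordance.  ``curve`` holds
    (FPR, TPR) points of the empirical ROC curve of the oriented score.
    """

    variables: tuple[str, ...]
    auc: float
    raw_auc: float
    orientation: int
    n_pos: int
    n_neg: int
    ties: int
    curve: np.ndarray = field(repr=False)
    note: str = ""

    @property
    def curve_auc(self) -> float:
        fpr, tpr = self.curve[:, 0], self.curve[:, 1]
        return float(np.trapezoid(tpr, fpr))


def _pair_count_auc(values: np.ndarray, labels: np.ndarray) -> tuple[float, int]:
    """Mann-Whitney concordance by exhaustive pair count; ties count 0.5."""
    pos = values[labels]
    neg = values[~labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg)), int(eq)


def _roc_curve(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Empirical ROC points (FPR, TPR), monotone from (0,0) to (1,1)."""
    order = np.argsort(-values, kind="stable")
    v = values[order]
    y = labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(v)) , len(v) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (~y).sum()]
    return np.column_stack([fpr, tpr])


def _as_binary(labels, positive=None) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype == bool:
        return lab
    uniq = sorted(pd.unique(lab).tolist())
    if len(uniq) != 2:
        raise ValueError(f"labels must be binary, got {uniq}")
    if positive is None:
        positive = "High" if "High" in uniq else uniq[1]
    return lab == positive


def mw_auc(values, labels, positive=None, variable: str = "score") -> ROCResult:
    """Mann-Whitney ROC AUC of one predictor against a binary label.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg); the
    orientation is chosen so the reported AUC is >= 0.5 and recorded in the
    result.  The trapezoidal area under the empirical ROC curve is checked
    to agree with the pair count.
    """
    v = np.asarray(values, dtype=float)
    y = _as_binary(labels, positive)
    if y.all() or not y.any():
        raise ValueError("both classes must be non-empty")
    if np.isnan(v).any():
        keep = ~np.isnan(v)
        v, y = v[keep], y[keep]
    raw, ties = _pair_count_auc(v, y)
    orientation = 1 if raw >= 0.5 else -1
    auc = raw if orientation == 1 else 1.0 - raw
    curve = _roc_curve(orientation * v, y)
    res = ROCResult(
        variables=(variable,), auc=float(auc), raw_auc=float(raw),
        orientation=orientation, n_pos=int(y.sum()), n_neg=int((~y).sum()),
        ties=ties, curve=curve,
    )
    if abs(res.curve_auc - res.auc) > 1e-9:
        raise AssertionError("ROC-curve area disagrees with the pair count")
    return res


def combined_auc(
    cohort: pd.DataFrame,
    variables: tuple[str, ...],
    labels=None,
    positive=None,
    n_bootstrap: int = 0,
    seed: int = 0,
) -> ROCResult:
    """In-sample AUC of the linear score of a logistic fit on standardised variables.

    The score is the linear predictor of an unpenalised logistic regression
    of the binary label on the z-scored variables; on separation the fit
    falls back to an L2-penalised one and the result is flagged in
    ``note``.  Optional seeded bootstrap percentile CI over refitted
    scores is appended to ``note``.
    """
    if len(variables) < 1:
        raise ValueError("at least one variable required")
    if labels is None:
        labels = cohort["outflow_category"]
    y = _as_binary(labels, positive)
    X = cohort.loc[:, list(variables)].to_numpy(float)
    score, note = _logistic_score(X, y)
    res = mw_auc(score, y, positive=True, variable="+".join(variables))
    res = ROCResult(
        variables=tuple(variables), auc=res.auc, raw_auc=res.raw_auc,
        orientation=res.orientation, n_pos=res.n_pos, n_neg=res.n_neg,
        ties=res.ties, curve=res.curve, note=note,
    )
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        aucs = []
        n = len(y)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            if y[idx].all() or not y[idx].any():
                continue
            s, _ = _logistic_score(X[idx], y[idx])
            aucs.append(mw_auc(s, y[idx], positive=True).auc)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        res.note = (res.note + f" bootstrap95=({lo:.3f},{hi:.3f})").strip()
    return res


def _logistic_score(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, str]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    import statsmodels.api as sm

    import warnings

    note = ""
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation is handled below
            fit = sm.Logit(y.astype(float), sm.add_constant(Z)).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)) or not fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge")
        score = sm.add_constant(Z) @ fit.params
    except Exception:
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0, max_iter=1000)
        lr.fit(Z, y)
        score = lr.decision_function(Z)
        note = "penalised fit (separation fallback)"
    return np.asarray(score, float), note


def compare_groups(
    cohort: pd.DataFrame,
    grouping: str = "outcome",
    variables: tuple[str, ...] = ANATOMICAL_VARIABLES,
    method: str = "rank-sum",
) -> pd.DataFrame:
    """Two-sided per-variable p-values between two groups.

    ``method`` is ``rank-sum`` (Mann-Whitney with tie correction; default,
    suited to small non-normal samples) or ``welch``.  Constant variables
    yield a missing p-value.  Groupings with more than two levels are
    compared via Kruskal-Wallis (rank-sum) / one-way ANOVA (welch).
    """
    df = cohort.copy()
    if grouping == "rcf":
        df["_group"] = np.where(df["fistula_type"] == "RCF", "RCF", "non-RCF")
        key = "_group"
    else:
        key = grouping
    groups = [sub for _, sub in df.groupby(key, sort=True)]
    if any(len(g) < 2 for g in groups) and method == "welch":
        raise ValueError("welch requires at least 2 records per group")
    rows = []
    for var in variables:
        samples = [g[var].dropna().to_numpy(float) for g in groups]
        allv = np.concatenate(samples)
        if np.ptp(allv) == 0:
            p = np.nan
        elif len(samples) == 2:
            if method == "rank-sum":
                p = sps.mannwhitneyu(samples[0], samples[1], alternative="two-sided").pvalue
            else:
                p = sps.ttest_ind(samples[0], samples[1], equal_var=False).pvalue
        else:
            if method == "rank-sum":
                p = sps.kruskal(*samples).pvalue
            else:
                p = sps.f_oneway(*samples).pvalue
        rows.append(dict(variable=var, method=method, p_value=float(p)))
    return pd.DataFrame(rows)


def roc_table(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ANATOMICAL_VARIABLES,
    labels=None,
) -> pd.DataFrame:
    """Single-variable Mann-Whitney AUCs against the High/Low outflow label."""
    if labels is None:
        labels = cohort["outflow_category"]
    rows = []
    for var in variables:
        r = mw_auc(cohort[var], labels, variable=var)
        rows.append(dict(variable=var, orientation=r.orientation, auc=r.auc,
                         n_pos=r.n_pos, n_neg=r.n_neg, ties=r.ties))
    return pd.DataFrame(rows)
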