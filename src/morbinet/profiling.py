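"""Social profiling of multimorbidity patterns.

Each respondent is assigned to the disease community (multimorbidity
pattern MP1..MPm) containing the largest number of their diagnosed
conditions; pattern membership is then modelled on age and occupation-based
social class by a baseline-category multinomial logit, reported as odds
ratios with Wald 95% confidence intervals and significance stars at the
0.05 / 0.01 / 0.001 levels.

The assignment rule is a package design choice (majority of diagnosed
conditions, with prevalence-weighted and index tie-breaks); assignments
carry a ``tie_flag`` so downstream readers can see where it fired.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from morbinet.mgm import _as_matrix
from morbinet.network_analysis import CommunityPartition, label_patterns
from morbinet.schema import Cohort

logger = logging.getLogger(__name__)


def assign_patterns(
    data: Union[Cohort, pd.DataFrame, np.ndarray],
    partition: CommunityPartition,
) -> pd.DataFrame:
    """Assign each individual to a multimorbidity pattern.

    The individual goes to the community with the largest count of their
    diagnosed conditions; ties go to the community with the larger summed
    prevalence of those conditions, then to the lower MP index. Rows with
    zero diagnosed conditions violate the upstream multimorbidity filter
    and raise.
    """
    X, _ = _as_matrix(data)
    n, p = X.shape
    if len(partition.membership) != p:
        raise ValueError("partition must cover all condition nodes")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError(
            "individual with zero diagnosed conditions; apply the "
            "multimorbidity filter first"
        )
    labels_tab = label_patterns(partition)
    mp_rank = {mp: int(mp[2:]) for mp in labels_tab["pattern"].unique()}
    mp_of_comm = dict(
        zip(labels_tab["community"].astype(int), labels_tab["pattern"])
    )
    prevalence = X.mean(axis=0)
    comm_labels = sorted(set(partition.membership.tolist()))
    # counts (n, n_comm) and prevalence-weighted counts per community
    masks = np.stack(
        [(partition.membership == c).astype(float) for c in comm_labels], axis=1
    )
    counts = X @ masks
    weighted = X @ (masks * prevalence[:, None])
    ranks = np.array([mp_rank[mp_of_comm[c]] for c in comm_labels])
    assigned, ties = [], []
    for i in range(n):
        cmax = counts[i].max()
        cand = np.flatnonzero(counts[i] == cmax)
        tie = len(cand) > 1
        if tie:
            wmax = weighted[i, cand].max()
            cand = cand[weighted[i, cand] == wmax]
            tie = True
        if len(cand) > 1:
            cand = cand[np.argsort(ranks[cand])][:1]
        assigned.append(mp_of_comm[comm_labels[int(cand[0])]])
        ties.append(tie)
    return pd.DataFrame({"row": np.arange(n), "pattern": assigned, "tie_flag": ties})


def _stars(p_value: float) -> str:
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def fit_multinomial(
    assignments: pd.DataFrame,
    covariates: pd.DataFrame,
    reference_pattern: str = "MP1",
    reference_class: Optional[Union[int, str]] = None,
    class_column: str = "social_class",
    age_column: str = "age",
    min_count: int = 25,
) -> pd.DataFrame:
    """Baseline-category multinomial logit of pattern membership.

    Age enters linearly in years; social class as dummies against
    ``reference_class`` (default: the lowest class code present). Pattern
    categories with fewer than ``min_count`` individuals are dropped with a
    warning (empty or near-empty categories make the shared likelihood
    separable). Returns one row per (non-reference pattern, term) with
    OR = exp(coef), Wald 95% CI = exp(coef +/- 1.96 SE), p-value and stars.
    """
    y = assignments["pattern"].astype(str).reset_index(drop=True)
    cov = covariates.reset_index(drop=True)
    if len(cov) != len(y):
        raise ValueError("assignments and covariates must align row-wise")
    complete = cov[[age_column, class_column]].notna().all(axis=1)
    if not complete.all():
        logger.warning(
            "dropping %d rows with missing covariates", int((~complete).sum())
        )
        y, cov = y[complete], cov[complete]
    counts = y.value_counts()
    rare = counts[counts < min_count].index.tolist()
    if rare:
        logger.warning(
            "dropping sparse pattern categories %s (fewer than %d rows)",
            sorted(rare), min_count,
        )
        keep = ~y.isin(rare)
        y, cov = y[keep].reset_index(drop=True), cov[keep].reset_index(drop=True)
    patterns = sorted(y.unique(), key=lambda s: (len(s), s))
    if len(patterns) < 2:
        raise ValueError("need at least 2 patterns present")
    if reference_pattern not in patterns:
        logger.warning(
            "reference pattern %s empty; using %s", reference_pattern, patterns[0]
        )
        reference_pattern = patterns[0]
    order = [reference_pattern] + [p for p in patterns if p != reference_pattern]
    y_codes = pd.Categorical(y, categories=order).codes

    classes = sorted(cov[class_column].unique())
    if reference_class is None:
        reference_class = classes[0]
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not present")
    design = pd.DataFrame({"age": cov[age_column].astype(float).to_numpy()})
    for c in classes:
        if c != reference_class:
            design[f"{class_column}_{c}"] = (cov[class_column] == c).astype(float).to_numpy()
    exog = sm.add_constant(design, has_constant="add")

    model = sm.MNLogit(y_codes, exog)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        try:
            res = model.fit(method="newton", maxiter=200, disp=False)
            if not np.all(np.isfinite(np.asarray(res.params))):
                raise RuntimeError("non-finite estimates")
        except Exception:
            res = model.fit(method="lbfgs", maxiter=5000, disp=False)

    params = np.asarray(res.params)  # (n_terms, n_patterns - 1)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    term_names = ["intercept"] + list(design.columns)
    rows = []
    for kcat, pat in enumerate(order[1:]):
        for t, term in enumerate(term_names):
            coef, se, pv = params[t, kcat], bse[t, kcat], pvals[t, kcat]
            separated = not np.isfinite(se) or se > 50
            lo = np.exp(coef - 1.96 * se) if not separated else 0.0
            hi = np.exp(coef + 1.96 * se) if not separated else np.inf
            rows.append(
                {
                    "pattern": pat,
                    "term": term,
                    "or": float(np.exp(coef)),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "p_value": float(pv),
                    "stars": _stars(float(pv)),
                    "separation_flag": bool(separated),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["reference_pattern"] = reference_pattern
    out.attrs["reference_class"] = reference_class
    return out
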