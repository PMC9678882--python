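"""Nodewise predictability of the fitted network.

For each condition node, in-sample classification accuracy (Acc) of its
selected nodewise model (predict 1 iff fitted probability >= 0.5) is
compared with the intercept-only (majority-class) accuracy via the
normalized accuracy

    nAcc = (Acc - Acc_intercept) / (1 - Acc_intercept),

which is 0 for an empty neighbourhood, 1 for perfect prediction, and
negative when the selected model misclassifies more than the majority rule.
"""

from __future__ import annotations

import logging
import math
from typing import Union

import numpy as np
import pandas as pd

from morbinet.mgm import MGMNetwork, build_design, _as_matrix
from morbinet.schema import Cohort
from morbinet.solver import _sigmoid

logger = logging.getLogger(__name__)


def node_accuracy(network: MGMNetwork, data, node: int) -> float:
    """In-sample accuracy of one node's selected model.

    Ties at fitted probability exactly 0.5 classify as 1.
    """
    X, _ = _as_matrix(data)
    fit = network.fits[node]
    design, terms, _ = build_design(X, node, network.config.k if network.config else 2)
    # align design columns with the fit's term order
    index = {t: c for c, t in enumerate(terms)}
    coef = fit.selected_coef
    eta = np.full(X.shape[0], coef[0])
    for c, t in enumerate(fit.terms):
        b = coef[1 + c]
        if b != 0.0 and t in index:
            eta = eta + design[:, index[t]] * b
    pred = (_sigmoid(eta) >= 0.5).astype(float)
    return float(np.mean(pred == X[:, node]))


def normalized_accuracy(acc: float, acc_intercept: float) -> float:
    """(acc - acc_intercept) / (1 - acc_intercept); NaN when undefined."""
    if acc_intercept >= 1.0:
        logger.warning("intercept accuracy is 1; normalized accuracy undefined")
        return math.nan
    return (acc - acc_intercept) / (1.0 - acc_intercept)


def predictability_table(
    network: MGMNetwork, data: Union[Cohort, pd.DataFrame, np.ndarray]
) -> pd.DataFrame:
    """Per-node Acc, intercept-model Acc, and nAcc (one row per condition)."""
    X, names = _as_matrix(data)
    rows = []
    for node, name in enumerate(network.node_names):
        prev = float(X[:, node].mean())
        acc_int = max(prev, 1.0 - prev)
        acc = node_accuracy(network, data, node)
        rows.append(
            {
                "node": node + 1,
                "name": name,
                "acc": acc,
                "acc_intercept": acc_int,
                "nacc": normalized_accuracy(acc, acc_int),
            }
        )
    return pd.DataFrame(rows)
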