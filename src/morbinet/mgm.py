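"""Sparse k-order mixed graphical model by nodewise penalized regression.

One L1-penalized logistic regression is fitted per condition node on all
other nodes (k=2) — plus all pairwise products of the other nodes when
diagnostic triads are allowed (k=3) — along a decreasing lambda path.
Lambda is selected per node by the extended Bayesian information criterion

    EBIC_gamma = -2 loglik + df ln(n) + 2 gamma df ln(d),

where df counts nonzero penalized coefficients and d the candidate terms
(gamma = 0 recovers BIC; larger gamma is more conservative), or by
K-fold cross-validated deviance. Selected neighbourhoods are combined into
an undirected weighted network by the AND (both directions nonzero) or OR
rule; edge weight is the mean absolute contributing coefficient, signed
when the contributing signs agree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from morbinet.schema import Cohort
from morbinet.solver import (
    fit_l1_logistic,
    lambda_max,
    log_likelihood,
)

logger = logging.getLogger(__name__)


class NodewiseError(RuntimeError):
    """Estimation failure carrying the responsible node."""

    def __init__(self, node: int, message: str):
        super().__init__(f"node {node}: {message}")
        self.node = node


@dataclass
class EstimationConfig:
    """Settings of the nodewise MGM estimator."""

    k: int = 2
    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    selector: str = "ebic"
    cv_folds: int = 10
    seed: int = 0
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.k not in (2, 3):
            raise ValueError("k must be 2 or 3")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.rule.lower() not in ("and", "or"):
            raise ValueError("rule must be 'and' or 'or'")
        if self.selector.lower() not in ("ebic", "cv"):
            raise ValueError("selector must be 'ebic' or 'cv'")
        self.rule = self.rule.lower()
        self.selector = self.selector.lower()


def build_design(
    X: np.ndarray, node: int, k: int
) -> tuple[np.ndarray, list[tuple[int, ...]], list[tuple[int, ...]]]:
    """Design matrix for one node's regression.

    k=2: columns are the other p-1 indicators. k=3: additionally all
    pairwise products x_j * x_l (j < l, both != node). Constant columns are
    excluded from the penalized terms (flagged in the third return value).

    Returns (design, terms, excluded_terms); ``terms[c]`` names the
    variable indices behind column c.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    others = [j for j in range(p) if j != node]
    cols = [X[:, j] for j in others]
    terms: list[tuple[int, ...]] = [(j,) for j in others]
    if k == 3:
        for j, l in combinations(others, 2):
            cols.append(X[:, j] * X[:, l])
            terms.append((j, l))
    keep, excluded = [], []
    for c, (col, term) in enumerate(zip(cols, terms)):
        if col.min() == col.max():
            excluded.append(term)
        else:
            keep.append(c)
    if excluded:
        logger.warning(
            "node %d: excluding %d constant design columns", node, len(excluded)
        )
    design = np.column_stack([cols[c] for c in keep]) if keep else np.empty((X.shape[0], 0))
    return design, [terms[c] for c in keep], excluded


def lambda_path(
    design: np.ndarray,
    response: np.ndarray,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
) -> np.ndarray:
    """Log-spaced decreasing lambda sequence from lambda_max down.

    lambda_max is the smallest penalty with an all-zero solution (KKT bound
    at the intercept-only fit).
    """
    response = np.asarray(response, dtype=float)
    if response.min() == response.max():
        raise ValueError("response is constant; node has zero variance")
    lmax = lambda_max(design, response)
    if lmax <= 0:
        raise ValueError("degenerate design: lambda_max is zero")
    return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)


def fit_penalized_node(
    design: np.ndarray,
    response: np.ndarray,
    lam: float,
    warm: Optional[tuple[float, np.ndarray]] = None,
    tol: float = 1e-7,
) -> tuple[np.ndarray, float]:
    """One penalized logistic fit: ((intercept, beta...), log-likelihood)."""
    b0, beta = fit_l1_logistic(design, np.asarray(response, float), lam, warm=warm, tol=tol)
    ll = log_likelihood(design, np.asarray(response, float), b0, beta)
    return np.concatenate([[b0], beta]), ll


def ebic(loglik: float, df: int, n: int, d: int, gamma: float) -> float:
    """Extended BIC: -2 loglik + df ln(n) + 2 gamma df ln(d)."""
    if df < 0 or n < 1 or d < 1:
        raise ValueError("require df >= 0, n >= 1, d >= 1")
    return -2.0 * loglik + df * np.log(n) + 2.0 * gamma * df * np.log(d)


@dataclass
class NodewiseFit:
    """The full regularization path of one node's regression."""

    node: int
    terms: list[tuple[int, ...]]
    excluded_terms: list[tuple[int, ...]]
    lambda_path: np.ndarray
    coef_path: np.ndarray  # (n_lambda, 1 + n_terms); column 0 = intercept
    loglik_path: np.ndarray
    df_path: np.ndarray
    ebic_path: Optional[np.ndarray] = None
    selected_index: Optional[int] = None

    @property
    def d(self) -> int:
        """Number of candidate penalized terms."""
        return len(self.terms)

    @property
    def selected_lambda(self) -> float:
        return float(self.lambda_path[self.selected_index])

    @property
    def selected_coef(self) -> np.ndarray:
        return self.coef_path[self.selected_index]

    def coefficient_of(self, term: tuple[int, ...]) -> float:
        """Selected-model coefficient of a term, 0 if excluded/absent."""
        try:
            c = self.terms.index(tuple(term))
        except ValueError:
            return 0.0
        return float(self.selected_coef[1 + c])


def fit_node_path(
    design: np.ndarray,
    response: np.ndarray,
    node: int,
    terms: list[tuple[int, ...]],
    excluded: list[tuple[int, ...]],
    config: EstimationConfig,
    lambdas: Optional[np.ndarray] = None,
) -> NodewiseFit:
    """Fit the whole lambda path for one node with warm starts."""
    y = np.asarray(response, dtype=float)
    if lambdas is None:
        lambdas = lambda_path(design, y, config.n_lambda, config.lambda_min_ratio)
    n = len(y)
    coefs = np.zeros((len(lambdas), 1 + design.shape[1]))
    logliks = np.zeros(len(lambdas))
    dfs = np.zeros(len(lambdas), dtype=int)
    warm = None
    for i, lam in enumerate(lambdas):
        coef, ll = fit_penalized_node(design, y, lam, warm=warm, tol=config.tol)
        warm = (coef[0], coef[1:])
        coefs[i] = coef
        logliks[i] = ll
        dfs[i] = int(np.count_nonzero(coef[1:]))
    d = max(design.shape[1], 1)
    ebics = np.array(
        [ebic(ll, df, n, d, config.gamma) for ll, df in zip(logliks, dfs)]
    )
    return NodewiseFit(
        node=node,
        terms=terms,
        excluded_terms=excluded,
        lambda_path=np.asarray(lambdas, float),
        coef_path=coefs,
        loglik_path=logliks,
        df_path=dfs,
        ebic_path=ebics,
    )


def select_lambda(
    fit: NodewiseFit,
    selector: str = "ebic",
    gamma: float = 0.25,
    cv_folds: int = 10,
    seed: int = 0,
    design: Optional[np.ndarray] = None,
    response: Optional[np.ndarray] = None,
    n: Optional[int] = None,
) -> float:
    """Select lambda along the fitted path; ties go to the larger lambda.

    EBIC: minimize EBIC_gamma over the path. CV: minimize mean out-of-fold
    deviance over ``cv_folds`` folds (deterministic split given ``seed``);
    requires ``design`` and ``response``.
    """
    if selector == "ebic":
        if n is None:
            n = len(response) if response is not None else None
        if n is None:
            raise ValueError("EBIC selection needs the sample size n")
        scores = np.array(
            [
                ebic(ll, df, n, max(fit.d, 1), gamma)
                for ll, df in zip(fit.loglik_path, fit.df_path)
            ]
        )
    elif selector == "cv":
        if design is None or response is None:
            raise ValueError("CV selection needs design and response")
        scores = _cv_deviance_path(design, np.asarray(response, float), fit.lambda_path, cv_folds, seed)
    else:
        raise ValueError(f"unknown selector {selector!r}")
    # path runs from largest lambda down; strict < keeps the earlier
    # (larger, sparser) lambda on ties
    best = 0
    for i in range(1, len(scores)):
        if scores[i] < scores[best]:
            best = i
    fit.selected_index = best
    fit.ebic_path = scores if selector == "ebic" else fit.ebic_path
    return float(fit.lambda_path[best])


def _cv_deviance_path(
    design: np.ndarray,
    y: np.ndarray,
    lambdas: np.ndarray,
    cv_folds: int,
    seed: int,
) -> np.ndarray:
    n = len(y)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv_folds)
    dev = np.zeros(len(lambdas))
    for hold in folds:
        mask = np.ones(n, dtype=bool)
        mask[hold] = False
        Xtr, ytr = design[mask], y[mask]
        Xte, yte = design[~mask], y[~mask]
        warm = None
        for i, lam in enumerate(lambdas):
            coef, _ = fit_penalized_node(Xtr, ytr, lam, warm=warm)
            warm = (coef[0], coef[1:])
            dev[i] += -2.0 * log_likelihood(Xte, yte, coef[0], coef[1:])
    return dev / n


@dataclass
class MGMNetwork:
    """A signed weighted comorbidity network from nodewise fits."""

    weights: np.ndarray
    sign_defined: np.ndarray
    triples: list[tuple[int, int, int, float]]
    config: EstimationConfig
    node_names: list[str]
    fits: list[NodewiseFit] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")

    @property
    def p(self) -> int:
        return self.weights.shape[0]

    def edges(self) -> set[tuple[int, int]]:
        """Unordered index pairs with nonzero weight."""
        i, j = np.nonzero(np.triu(self.weights, 1))
        return set(zip(i.tolist(), j.tolist()))

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, j in sorted(self.edges()):
            rows.append(
                {
                    "node_i": self.node_names[i],
                    "node_j": self.node_names[j],
                    "weight": self.weights[i, j],
                    "sign_defined": bool(self.sign_defined[i, j]),
                }
            )
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight", "sign_defined"])

    def triple_list(self) -> pd.DataFrame:
        rows = [
            {
                "node_i": self.node_names[i],
                "node_j": self.node_names[j],
                "node_l": self.node_names[l],
                "weight": w,
            }
            for i, j, l, w in self.triples
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "node_l", "weight"])

    @property
    def selected_lambdas(self) -> list[float]:
        return [f.selected_lambda for f in self.fits]

    def to_graphml(self, path) -> None:
        """Write the network as GraphML (nodes named, weights as attributes)."""
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self.node_names)
        for i, j in sorted(self.edges()):
            G.add_edge(
                self.node_names[i],
                self.node_names[j],
                weight=float(self.weights[i, j]),
                sign_defined=bool(self.sign_defined[i, j]),
            )
        nx.write_graphml(G, path)


def aggregate_network(
    fits: Sequence[NodewiseFit],
    rule: str,
    node_names: Sequence[str],
    config: Optional[EstimationConfig] = None,
) -> MGMNetwork:
    """Combine selected nodewise neighbourhoods into one undirected network.

    A pairwise edge (i, j) requires the coefficient of j in node i's model
    and/or the coefficient of i in node j's model to be nonzero (AND / OR
    rule). Weight = mean of the two absolute coefficients (zeros included
    under OR); the consensus sign is attached when all contributing signs
    agree, otherwise the weight stays positive with ``sign_defined`` False.
    A k=3 triple requires the product term in all (AND) / any (OR) of the
    three nodewise models; its weight is the mean absolute product-term
    coefficient over the three.
    """
    rule = rule.lower()
    p = len(fits)
    weights = np.zeros((p, p))
    sign_ok = np.ones((p, p), dtype=bool)
    for i in range(p):
        for j in range(i + 1, p):
            a = fits[i].coefficient_of((j,))
            b = fits[j].coefficient_of((i,))
            present = (a != 0 and b != 0) if rule == "and" else (a != 0 or b != 0)
            if not present:
                continue
            w = (abs(a) + abs(b)) / 2.0
            signs = {np.sign(c) for c in (a, b) if c != 0}
            if len(signs) == 1:
                weights[i, j] = weights[j, i] = signs.pop() * w
            else:
                weights[i, j] = weights[j, i] = w
                sign_ok[i, j] = sign_ok[j, i] = False
    triples: list[tuple[int, int, int, float]] = []
    if any(len(t) == 2 for f in fits for t in f.terms):
        for i, j, l in combinations(range(p), 3):
            cs = [
                fits[i].coefficient_of((j, l) if j < l else (l, j)),
                fits[j].coefficient_of((i, l) if i < l else (l, i)),
                fits[l].coefficient_of((i, j) if i < j else (j, i)),
            ]
            nz = [c for c in cs if c != 0]
            present = len(nz) == 3 if rule == "and" else len(nz) >= 1
            if present:
                triples.append((i, j, l, float(np.mean(np.abs(cs)))))
    return MGMNetwork(
        weights=weights,
        sign_defined=sign_ok,
        triples=triples,
        config=config,
        node_names=list(node_names),
        fits=list(fits),
    )


def _as_matrix(data: Union[Cohort, pd.DataFrame, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, Cohort):
        m = data.analysis_matrix()
        return m.to_numpy(dtype=float), list(m.columns)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), list(data.columns)
    arr = np.asarray(data, dtype=float)
    return arr, [f"v{i + 1}" for i in range(arr.shape[1])]


def fit_mgm(
    data: Union[Cohort, pd.DataFrame, np.ndarray],
    config: Optional[EstimationConfig] = None,
) -> MGMNetwork:
    """Estimate the k-order MGM over all condition nodes of a cohort.

    Orchestrates design construction, the lambda path, penalized fits with
    warm starts, lambda selection, and AND/OR aggregation. Deterministic
    given ``config.seed``.
    """
    config = config or EstimationConfig()
    X, names = _as_matrix(data)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 condition nodes")
    fits = []
    for node in range(p):
        y = X[:, node]
        try:
            design, terms, excluded = build_design(X, node, config.k)
            fit = fit_node_path(design, y, node, terms, excluded, config)
            select_lambda(
                fit,
                selector=config.selector,
                gamma=config.gamma,
                cv_folds=config.cv_folds,
                seed=config.seed,
                design=design,
                response=y,
                n=n,
            )
        except Exception as exc:  # re-raise with node identity
            raise NodewiseError(node, str(exc)) from exc
        fits.append(fit)
    return aggregate_network(fits, config.rule, names, config)
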