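"""Pairwise linear baselines and per-subject parenclitic (deviation) networks.

For every unordered feature pair {k, l} (index order k < l) an ordinary
least-squares line is fitted on the reference population (survivors),

    f_l = alpha_{k,l} + beta_{k,l} * f_k + eps_{k,l},

and sigma_{k,l} is the sample standard deviation of the residual vector.
A subject h is then mapped to a fully weighted graph over the features with

    w_{k,l} = (f_{h,l} - (alpha_{k,l} + beta_{k,l} * f_{h,k})) / sigma_{k,l},

the Z-score of the subject's distance from the reference relation. Large
|w| on a pair means the subject deviates from the behaviour the reference
population exhibits on that pair. Binarization keeps links with |w| strictly
above a threshold (default 0.5; |w| <= threshold discarded).

Pairs are stored in condensed upper-triangular order (numpy ``triu_indices``
row-major), one record per unordered pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

logger = logging.getLogger(__name__)

#: sigma below this is treated as an exact linear dependence -> degenerate pair
SIGMA_TOL = 1e-8
#: predictor variance below this cannot support a regression -> degenerate pair
VAR_TOL = 1e-12


class InsufficientDataError(ValueError):
    pass


def pair_indices(n_features: int) -> tuple[np.ndarray, np.ndarray]:
    """Condensed pair order: (k, l) with k < l, row-major."""
    return np.triu_indices(n_features, k=1)


def condensed_to_square(values: np.ndarray, n_features: int,
                        dtype=None) -> np.ndarray:
    k, l = pair_indices(n_features)
    out = np.zeros((n_features, n_features),
                   dtype=dtype if dtype is not None else values.dtype)
    out[k, l] = values
    out[l, k] = values
    return out


@dataclass
class BaselineModel:
    """OLS baselines for every unordered feature pair, fitted on controls.

    ``alpha``, ``beta``, ``sigma`` and ``degenerate`` are condensed vectors of
    length ``n_f * (n_f - 1) / 2`` in ``pair_indices`` order. ``sigma`` is the
    sample standard deviation (ddof=1) of the training residuals. A pair is
    degenerate when the predictor has (numerically) zero variance or the
    residual spread is below tolerance; degenerate pairs never carry a link.
    """

    feature_names: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    degenerate: np.ndarray
    n_train: int

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_pairs(self) -> int:
        return len(self.alpha)

    def zscores(self, X: np.ndarray) -> np.ndarray:
        """Residual Z-score matrix, shape (n_subjects, n_pairs).

        Degenerate pairs and pairs touching a missing (NaN) value get 0.
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"subject has {X.shape[1]} features, model expects {self.n_features}")
        k, l = pair_indices(self.n_features)
        safe_sigma = np.where(self.degenerate, 1.0, self.sigma)
        with np.errstate(invalid="ignore"):
            w = (X[:, l] - (self.alpha + self.beta * X[:, k])) / safe_sigma
        w[:, self.degenerate] = 0.0
        missing = ~np.isfinite(w)
        if missing.any():
            logger.warning("%d pair values skipped due to missing data",
                           int(missing.sum()))
            w[missing] = 0.0
        return w

    def to_frame(self) -> pd.DataFrame:
        k, l = pair_indices(self.n_features)
        names = np.asarray(self.feature_names)
        return pd.DataFrame({
            "feature_k": names[k],
            "feature_l": names[l],
            "alpha": self.alpha,
            "beta": self.beta,
            "sigma": self.sigma,
            "n_train": self.n_train,
            "degenerate": self.degenerate.astype(int),
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BaselineModel":
        frame = pd.read_csv(path)
        names: list[str] = []
        for name in pd.concat([frame["feature_k"], frame["feature_l"]]):
            if name not in names:
                names.append(name)
        n_f = len(names)
        if len(frame) != n_f * (n_f - 1) // 2:
            raise ValueError("baseline CSV does not cover all unordered pairs")
        index = {n: i for i, n in enumerate(names)}
        order = np.lexsort((frame["feature_l"].map(index),
                            frame["feature_k"].map(index)))
        frame = frame.iloc[order]
        return cls(
            feature_names=names,
            alpha=frame["alpha"].to_numpy(float),
            beta=frame["beta"].to_numpy(float),
            sigma=frame["sigma"].to_numpy(float),
            degenerate=frame["degenerate"].to_numpy(bool),
            n_train=int(frame["n_train"].iloc[0]),
        )


def fit_baseline(controls: Cohort | pd.DataFrame,
                 feature_names: list[str] | None = None,
                 *, sigma_tol: float = SIGMA_TOL,
                 var_tol: float = VAR_TOL) -> BaselineModel:
    """Fit the per-pair OLS baselines on a control (reference) population.

    One regression per unordered pair: the higher-index feature is regressed
    on the lower-index feature. Requires at least 3 control subjects.
    """
    if isinstance(controls, Cohort):
        frame = controls.frame[controls.feature_names
                               if feature_names is None else feature_names]
    else:
        frame = controls if feature_names is None else controls[feature_names]
    feature_names = list(frame.columns)
    for name in feature_names:
        if not np.issubdtype(frame[name].dtype, np.number):
            raise TypeError(f"feature {name!r} is not numeric")
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 control subjects, got {n}")
    mu = X.mean(axis=0)
    C = X - mu
    S = C.T @ C  # centred cross-products
    k, l = pair_indices(len(feature_names))
    s_kk = S[k, k]
    zero_var = s_kk / (n - 1) < var_tol
    safe_skk = np.where(zero_var, 1.0, s_kk)
    beta = S[k, l] / safe_skk
    alpha = mu[l] - beta * mu[k]
    ssr = np.maximum(S[l, l] - S[k, l] ** 2 / safe_skk, 0.0)
    sigma = np.sqrt(ssr / (n - 1))
    degenerate = zero_var | (sigma < sigma_tol)
    beta[zero_var] = 0.0
    alpha[zero_var] = mu[l][zero_var]
    sigma[zero_var] = np.sqrt(np.maximum(S[l, l][zero_var], 0.0) / (n - 1))
    degenerate = degenerate | (sigma < sigma_tol)
    return BaselineModel(feature_names=feature_names, alpha=alpha, beta=beta,
                         sigma=sigma, degenerate=degenerate, n_train=n)


@dataclass
class ParencliticNetwork:
    """Per-subject weighted deviation graph over the model's features.

    ``weights`` is the condensed vector of residual Z-scores; ``binary`` (set
    by :func:`binarize`) is the condensed 0/1 adjacency after thresholding.
    """

    subject_id: str
    feature_names: list[str]
    weights: np.ndarray
    binary: np.ndarray | None = None
    threshold: float | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.feature_names)

    def weight_matrix(self) -> np.ndarray:
        return condensed_to_square(self.weights, self.n_nodes)

    def adjacency_matrix(self) -> np.ndarray:
        if self.binary is None:
            raise ValueError("network not binarized; call binarize() first")
        return condensed_to_square(self.binary.astype(np.uint8), self.n_nodes)

    def to_edge_list(self) -> pd.DataFrame:
        """All pairs as rows ``source,target,weight[,binary]``."""
        k, l = pair_indices(self.n_nodes)
        names = np.asarray(self.feature_names)
        data = {"source": names[k], "target": names[l], "weight": self.weights}
        if self.binary is not None:
            data["binary"] = self.binary.astype(int)
        return pd.DataFrame(data)

    def to_networkx(self, binary_only: bool = False):
        import networkx as nx

        g = nx.Graph(subject_id=self.subject_id)
        g.add_nodes_from(self.feature_names)
        k, l = pair_indices(self.n_nodes)
        names = self.feature_names
        for i in range(len(k)):
            if binary_only:
                if self.binary is None or not self.binary[i]:
                    continue
            elif self.weights[i] == 0.0:
                continue
            attrs = {"weight": float(self.weights[i])}
            if self.binary is not None:
                attrs["binary"] = int(self.binary[i])
            g.add_edge(names[k[i]], names[l[i]], **attrs)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_edge_list(cls, edges: pd.DataFrame | str,
                       subject_id: str = "subject") -> "ParencliticNetwork":
        """Rebuild a network from a ``source,target,weight[,binary]`` table."""
        if not isinstance(edges, pd.DataFrame):
            edges = pd.read_csv(edges)
        names: list[str] = []
        for name in pd.concat([edges["source"], edges["target"]]):
            if name not in names:
                names.append(name)
        n = len(names)
        index = {v: i for i, v in enumerate(names)}
        k, l = pair_indices(n)
        pos = {(k[i], l[i]): i for i in range(len(k))}
        weights = np.zeros(len(k))
        binary = np.zeros(len(k), dtype=bool) if "binary" in edges else None
        for row in edges.itertuples(index=False):
            a, b = sorted((index[row.source], index[row.target]))
            weights[pos[(a, b)]] = row.weight
            if binary is not None:
                binary[pos[(a, b)]] = bool(row.binary)
        return cls(subject_id=subject_id, feature_names=names,
                   weights=weights, binary=binary)

    @classmethod
    def from_graphml(cls, path,
                     subject_id: str | None = None) -> "ParencliticNetwork":
        """Rebuild a network from a GraphML file written by this package."""
        import networkx as nx

        g = nx.read_graphml(path)
        names = list(g.nodes)
        n = len(names)
        index = {v: i for i, v in enumerate(names)}
        k, l = pair_indices(n)
        pos = {(k[i], l[i]): i for i in range(len(k))}
        weights = np.zeros(len(k))
        has_binary = any("binary" in d for _, _, d in g.edges(data=True))
        binary = np.zeros(len(k), dtype=bool) if has_binary else None
        for u, v, data in g.edges(data=True):
            a, b = sorted((index[u], index[v]))
            weights[pos[(a, b)]] = float(data.get("weight", 0.0))
            if binary is not None:
                binary[pos[(a, b)]] = bool(int(data.get("binary", 0)))
        if subject_id is None:
            subject_id = str(g.graph.get("subject_id", "subject"))
        return cls(subject_id=subject_id, feature_names=names,
                   weights=weights, binary=binary)


def compute_network(subject, model: BaselineModel,
                    subject_id: str = "subject") -> ParencliticNetwork:
    """Build one subject's weighted deviation network from a fitted model.

    ``subject`` is a mapping / pandas Series of feature name -> value; it
    must contain every model feature. Missing (NaN) values silence the pairs
    they touch (weight 0, with a logged warning).
    """
    if isinstance(subject, pd.Series):
        subject_id = str(subject.name) if subject.name is not None else subject_id
        mapping = subject
    else:
        mapping = pd.Series(dict(subject))
    missing_names = [n for n in model.feature_names if n not in mapping.index]
    if missing_names:
        raise KeyError(f"subject lacks model features: {missing_names}")
    values = mapping[model.feature_names].to_numpy(dtype=float)
    weights = model.zscores(values[None, :])[0]
    return ParencliticNetwork(subject_id=subject_id,
                              feature_names=list(model.feature_names),
                              weights=weights)


def compute_networks(cohort: Cohort, model: BaselineModel) -> list[ParencliticNetwork]:
    """Vectorized :func:`compute_network` over every subject in a cohort."""
    W = model.zscores(cohort.feature_matrix(model.feature_names))
    return [ParencliticNetwork(subject_id=str(sid),
                               feature_names=list(model.feature_names),
                               weights=W[i])
            for i, sid in enumerate(cohort.subject_ids)]


def binarize(network: ParencliticNetwork,
             threshold: float = 0.5) -> ParencliticNetwork:
    """Threshold |w|: links kept for |w| strictly greater than ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return ParencliticNetwork(
        subject_id=network.subject_id,
        feature_names=list(network.feature_names),
        weights=network.weights,
        binary=np.abs(network.weights) > threshold,
        threshold=threshold,
    )
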