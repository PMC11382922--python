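"""Feature-importance analyses for boosted-tree ensembles.

Six methods: the five split-record metrics of the XGBoost family —

* ``weight``      number of splits on the feature
* ``gain``        mean split gain
* ``total_gain``  summed split gain
* ``cover``       mean cover (sum of Hessians h over the splitting node)
* ``total_cover`` summed cover

— plus ``shap``: mean |φ| of per-sample tree-Shapley attributions on the margin
scale, with conditional expectations weighted by training cover (node sample
counts). All five tree metrics derive from the same split records, so their
nonzero supports are identical by construction; SHAP support is a subset (a
feature absent from every split has zero attribution on every sample).

For a federated model each party contributes the records of the nodes it owns
and the guest aggregates — no feature data crosses parties, since gain and
cover are attached to the split record during training.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .boosting import BoostedModel, Tree
from .data import DataError, ParameterError
from .federation import FederatedBoostedModel

TREE_METHODS = ("weight", "gain", "total_gain", "cover", "total_cover")
ALL_METHODS = TREE_METHODS + ("shap",)

_MAX_TREE_FEATURES = 16  # exact Shapley enumerates 2^u subsets per tree


class ComparisonError(ValueError):
    """Importance reports from different models cannot be compared."""


def _fingerprint(model: BoostedModel | FederatedBoostedModel) -> str:
    if isinstance(model, FederatedBoostedModel):
        model = model.as_centralized()
    return hashlib.sha256(model.to_json().encode()).hexdigest()


def _iter_splits(model: BoostedModel | FederatedBoostedModel):
    """Yield (feature, gain, cover) for every internal node of every tree."""
    if isinstance(model, FederatedBoostedModel):
        for shard in model.shards.values():
            for rec in shard.splits.values():
                yield rec.feature, rec.gain, rec.cover
    else:
        for tree in model.trees:
            for node in tree.nodes:
                if not node.is_leaf:
                    yield node.feature, node.gain, node.cover


def _split_table(model) -> pd.DataFrame:
    names = model.feature_names
    weight = pd.Series(0, index=names, dtype=np.int64)
    gain_sum = pd.Series(0.0, index=names)
    cover_sum = pd.Series(0.0, index=names)
    for feature, gain, cover in _iter_splits(model):
        weight[feature] += 1
        gain_sum[feature] += gain
        cover_sum[feature] += cover
    w = weight.to_numpy().astype(float)
    with np.errstate(invalid="ignore"):
        gain_mean = np.where(w > 0, gain_sum.to_numpy() / np.maximum(w, 1), 0.0)
        cover_mean = np.where(w > 0, cover_sum.to_numpy() / np.maximum(w, 1), 0.0)
    # totals as mean*weight keeps gain×weight == total_gain exact in floats
    return pd.DataFrame(
        {
            "weight": weight,
            "gain": gain_mean,
            "cover": cover_mean,
            "total_gain": gain_mean * w,
            "total_cover": cover_mean * w,
        },
        index=pd.Index(names, name="feature"),
    )


def tree_importance(
    model: BoostedModel | FederatedBoostedModel, method: str
) -> pd.Series:
    """One importance column (per-feature scores) for a split-record method."""
    if method not in TREE_METHODS:
        raise ParameterError(
            f"unknown method {method!r}; expected one of {TREE_METHODS}"
        )
    table = _split_table(model)
    out = table[method].astype(float).copy()
    out.attrs["method"] = method
    out.attrs["model_fingerprint"] = _fingerprint(model)
    return out


# ---------------------------------------------------------------------------
# Tree-Shapley


def _tree_used_features(tree: Tree) -> list[str]:
    seen: list[str] = []
    for node in tree.nodes:
        if not node.is_leaf and node.feature not in seen:
            seen.append(node.feature)
    return seen


def _expvalue(tree: Tree, node_id: int, in_S: dict[str, int], X: np.ndarray) -> np.ndarray:
    """Cover-weighted conditional expectation E[f(x) | x_S] for all rows of X.

    Features in S route by value; features out of S are marginalized with the
    training-sample fractions of each child.
    """
    node = tree.nodes[node_id]
    if node.is_leaf:
        return np.full(X.shape[0], node.weight)
    left = tree.nodes[node.left]
    right = tree.nodes[node.right]
    col = in_S.get(node.feature)
    vl = _expvalue(tree, node.left, in_S, X)
    vr = _expvalue(tree, node.right, in_S, X)
    if col is not None:
        return np.where(X[:, col] < node.threshold, vl, vr)
    total = left.n_samples + right.n_samples
    return (left.n_samples / total) * vl + (right.n_samples / total) * vr


def shap_values(model: BoostedModel, X) -> tuple[np.ndarray, float]:
    """Per-feature Shapley attributions φ on the margin scale, plus base value.

    Exact Shapley over each tree's used feature set (at most 2^depth − 1
    features per tree), with the cover-weighted conditional-expectation value
    function. Satisfies local accuracy: base + Σφ equals the model margin for
    every row.
    """
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise DataError(f"row missing used feature: {missing[0]!r}")
        Xm = X[model.feature_names].to_numpy(dtype=np.float64)
    else:
        Xm = np.asarray(X, dtype=np.float64)
        if Xm.ndim == 1:
            Xm = Xm[None, :]
    n, d = Xm.shape[0], len(model.feature_names)
    col_of = {f: i for i, f in enumerate(model.feature_names)}
    phi = np.zeros((n, d))
    base = model.config.base_margin
    lr = model.config.learning_rate
    for tree in model.trees:
        used = _tree_used_features(tree)
        u = len(used)
        if u > _MAX_TREE_FEATURES:
            raise ParameterError(
                f"tree uses {u} features; exact Shapley supports up to "
                f"{_MAX_TREE_FEATURES}"
            )
        base += lr * float(_expvalue(tree, 0, {}, Xm[:1])[0])
        if u == 0:
            continue
        # cache v(S) per subset bitmask
        values: dict[int, np.ndarray] = {}
        for r in range(u + 1):
            for subset in combinations(range(u), r):
                mask = sum(1 << i for i in subset)
                in_S = {used[i]: col_of[used[i]] for i in subset}
                values[mask] = _expvalue(tree, 0, in_S, Xm)
        for i, fname in enumerate(used):
            others = [j for j in range(u) if j != i]
            contrib = np.zeros(n)
            for r in range(u):
                w = 1.0 / (u * comb(u - 1, r))
                for subset in combinations(others, r):
                    mask = sum(1 << j for j in subset)
                    contrib += w * (values[mask | (1 << i)] - values[mask])
            phi[:, col_of[fname]] += lr * contrib
    return phi, float(base)


def shap_importance(
    model: BoostedModel | FederatedBoostedModel, X_reference
) -> pd.Series:
    """Global SHAP column: mean |φ| over the reference sample set."""
    fingerprint = _fingerprint(model)
    if isinstance(model, FederatedBoostedModel):
        model = model.as_centralized()
    phi, _ = shap_values(model, X_reference)
    out = pd.Series(
        np.abs(phi).mean(axis=0),
        index=pd.Index(model.feature_names, name="feature"),
    )
    out.attrs["method"] = "shap"
    out.attrs["model_fingerprint"] = fingerprint
    return out


# ---------------------------------------------------------------------------
# Reports and selection


def importance_report(
    model: BoostedModel | FederatedBoostedModel, X_reference=None
) -> pd.DataFrame:
    """All-method report in the appendix layout (feature, shap, weight, gain, …)."""
    table = _split_table(model)
    cols = {}
    if X_reference is not None:
        cols["shap"] = shap_importance(model, X_reference)
    for m in TREE_METHODS:
        cols[m] = table[m]
    report = pd.DataFrame(cols)
    order = ["shap"] if X_reference is not None else []
    report = report[order + ["weight", "gain", "cover", "total_gain", "total_cover"]]
    report.attrs["model_fingerprint"] = _fingerprint(model)
    return report


def select_top_k(scores: pd.Series | pd.DataFrame, method: str | None = None, k: int = 165) -> list[str]:
    """Top-k feature names by a metric, descending; ties by name ascending."""
    if k < 1:
        raise ParameterError("k must be >= 1")
    if isinstance(scores, pd.DataFrame):
        if method is None:
            raise ParameterError("method required when passing a full report")
        scores = scores[method]
    df = pd.DataFrame({"value": scores.astype(float), "name": scores.index.astype(str)})
    df = df.sort_values(["value", "name"], ascending=[False, True], kind="mergesort")
    return df["name"].head(k).tolist()


@dataclass
class AgreementResult:
    supports_identical: bool
    shap_support_subset: bool | None
    support: set[str]
    spearman: pd.DataFrame


def agreement_report(reports: dict[str, pd.Series]) -> AgreementResult:
    """Cross-method support identity and rank-correlation table.

    Asserts the five tree-metric nonzero supports are identical and SHAP
    support (if present) is a subset; reports pairwise Spearman correlations.
    Reports must come from the same model (fingerprint check).
    """
    fingerprints = {
        s.attrs.get("model_fingerprint") for s in reports.values()
    }
    if len(fingerprints) > 1:
        raise ComparisonError("importance reports come from different models")
    tree_reports = {m: reports[m] for m in TREE_METHODS if m in reports}
    supports = {m: set(s.index[s.to_numpy() != 0]) for m, s in tree_reports.items()}
    ref = next(iter(supports.values()), set())
    supports_identical = all(sup == ref for sup in supports.values())
    shap_subset = None
    if "shap" in reports:
        shap_support = set(
            reports["shap"].index[reports["shap"].to_numpy() != 0]
        )
        shap_subset = shap_support <= ref
    methods = list(reports)
    corr = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for a, b in combinations(methods, 2):
        rho = stats.spearmanr(
            reports[a].to_numpy(), reports[b].reindex(reports[a].index).to_numpy()
        ).statistic
        corr.loc[a, b] = corr.loc[b, a] = rho
    return AgreementResult(
        supports_identical=supports_identical,
        shap_support_subset=shap_subset,
        support=ref,
        spearman=corr,
    )
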