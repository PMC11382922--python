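"""In-process guest/host protocol for vertically federated gradient boosting.

One labeled party (the *guest*, party 0) computes per-sample gradients, seals
them, and drives tree growth; unlabeled *hosts* bin their own features locally,
aggregate sealed gradients into per-bin histograms, and own the split records
(feature + threshold) of the nodes split on their features. The guest only ever
learns the owning party id and a bin index for host-owned nodes; hosts never see
labels or unsealed gradients. Every cross-party exchange goes through a
:class:`Message` on an in-process transport, so the information-flow claims are
checkable on the transcript (:func:`privacy_audit`).

The trainer is engineered to be *bit-identical* to the centralized
:func:`~pufedboost.boosting.fit_boosting` on the column-concatenated data: both
share the histogram, split-search and leaf-weight code, scan features in the
same global order, and break ties lexicographically.

Encryption is modeled as a sealing contract with a pluggable backend; the
default backend is plaintext-with-audit. Hosts can aggregate sealed values into
histograms but have no reading interface.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .boosting import (
    MARGIN_CLIP,
    BoostConfig,
    BoostedModel,
    GradientPair,
    Histogram,
    Tree,
    TreeNode,
    assign_leaf_weights,
    build_histogram,
    compute_gradients,
    find_best_split,
    quantile_bin,
)
from .data import (
    DataError,
    SampleTable,
    VerticalPartition,
    WorkingLabels,
    vertical_split,
)


class ProtocolError(RuntimeError):
    """Violated protocol precondition (misaligned views, unknown party)."""


# ---------------------------------------------------------------------------
# Sealing


class SealedGradients:
    """Opaque per-sample gradient container handed to hosts.

    The host-facing surface is :meth:`histogram` only — additive aggregation
    into per-bin sums. The raw values are private to the sealing backend.
    """

    def __init__(self, grads: GradientPair, backend: "PlainSealingBackend"):
        self.__grads = grads
        self.__backend = backend

    def histogram(self, codes, node_idx, n_bins_per_feature) -> "SealedHistogram":
        hist = build_histogram(codes, self.__grads, node_idx, n_bins_per_feature)
        return SealedHistogram(hist, self.__backend)

    def _open(self, backend) -> GradientPair:
        if backend is not self.__backend:
            raise ProtocolError("sealed gradients opened with a foreign backend")
        return self.__grads

    def _digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.__grads.g.tobytes())
        h.update(self.__grads.h.tobytes())
        return h.hexdigest()


class SealedHistogram:
    """Per-bin sealed (G, H) sums; bin counts are public aggregates."""

    def __init__(self, hist: Histogram, backend: "PlainSealingBackend"):
        self.__hist = hist
        self.__backend = backend
        self.counts = [c.copy() for c in hist.count]

    def _open(self, backend) -> Histogram:
        if backend is not self.__backend:
            raise ProtocolError("sealed histogram opened with a foreign backend")
        return self.__hist

    def _digest(self) -> str:
        h = hashlib.sha256()
        for G, H, c in zip(self.__hist.G, self.__hist.H, self.__hist.count):
            h.update(G.tobytes())
            h.update(H.tobytes())
            h.update(c.tobytes())
        return h.hexdigest()


class PlainSealingBackend:
    """Default backend: plaintext values behind the sealing interface.

    Guarantees come from the interface plus the transcript audit, not from
    cryptography. A homomorphic backend can implement the same two methods.
    """

    def seal(self, grads: GradientPair) -> SealedGradients:
        return SealedGradients(grads, self)

    def unseal_histogram(self, sealed: SealedHistogram) -> Histogram:
        return sealed._open(self)

    def unseal_gradients(self, sealed: SealedGradients) -> GradientPair:
        return sealed._open(self)


# ---------------------------------------------------------------------------
# Messages


MESSAGE_KINDS = frozenset(
    {
        "gradients",
        "histogram",
        "split_broadcast",
        "split_answer",
        "leaf_assignment",
        "routing_query",
        "routing_answer",
    }
)

GUEST_TO_HOST_KINDS = frozenset(
    {"gradients", "leaf_assignment", "split_broadcast", "routing_query"}
)
HOST_TO_GUEST_KINDS = frozenset({"histogram", "split_answer", "routing_answer"})


@dataclass
class Message:
    sender: int
    receiver: int
    kind: str
    payload: dict


@dataclass
class MessageLog:
    messages: list[Message] = field(default_factory=list)

    def append(self, msg: Message) -> None:
        self.messages.append(msg)

    def __len__(self) -> int:
        return len(self.messages)

    def __iter__(self):
        return iter(self.messages)

    def digest(self) -> list[tuple[int, int, str, str]]:
        """Deterministic (sender, receiver, kind, payload-hash) sequence."""
        out = []
        for m in self.messages:
            canon = json.dumps(_canon(m.payload), sort_keys=True)
            h = hashlib.sha256(canon.encode()).hexdigest()
            out.append((m.sender, m.receiver, m.kind, h))
        return out


def _canon(obj):
    if isinstance(obj, dict):
        return {str(k): _canon(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canon(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (SealedGradients, SealedHistogram)):
        return {"__sealed__": type(obj).__name__, "digest": obj._digest()}
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class InProcessTransport:
    """Synchronous in-process delivery with an append-only transcript."""

    def __init__(self) -> None:
        self.log = MessageLog()
        self._handlers: dict[int, Callable[[Message], list[Message]]] = {}

    def register(self, party: int, handler: Callable[[Message], list[Message]]) -> None:
        self._handlers[party] = handler

    def send(self, msg: Message) -> list[Message]:
        self.log.append(msg)
        handler = self._handlers.get(msg.receiver)
        replies = handler(msg) if handler is not None else []
        for r in replies:
            self.log.append(r)
        return replies


# ---------------------------------------------------------------------------
# Parties and the federated model


@dataclass
class SplitRecord:
    feature: str
    bin: int
    threshold: float
    gain: float
    cover: float


@dataclass
class PartyShard:
    """What one party persists: its bin edges and its owned split records."""

    party: int
    edges: dict[str, np.ndarray] = field(default_factory=dict)
    splits: dict[tuple[int, int], SplitRecord] = field(default_factory=dict)


@dataclass
class FederatedBoostedModel:
    """Shared tree topology + ownership-partitioned node records.

    The guest-side ``trees`` carry feature/threshold only for guest-owned nodes;
    host-owned internal nodes carry the owning party id alone. Each party's
    :class:`PartyShard` holds the records for the nodes it owns.
    """

    feature_names: list[str]
    assignment: dict[str, int]
    config: BoostConfig
    trees: list[Tree] = field(default_factory=list)
    owners: list[dict[int, int]] = field(default_factory=list)  # per tree: node -> party
    shards: dict[int, PartyShard] = field(default_factory=dict)

    @property
    def parties(self) -> list[int]:
        return sorted(self.shards)

    def as_centralized(self) -> BoostedModel:
        """Merge all shards into one plain ensemble.

        Simulator-side convenience: in a deployment no single party could do
        this. Used for oracle comparison, importance and SHAP.
        """
        edges = [
            self.shards[self.assignment[f]].edges[f] for f in self.feature_names
        ]
        model = BoostedModel(
            feature_names=list(self.feature_names), edges=edges, config=self.config
        )
        for t, (tree, owner_map) in enumerate(zip(self.trees, self.owners)):
            merged = Tree(nodes=[copy.copy(n) for n in tree.nodes])
            for node in merged.nodes:
                if not node.is_leaf and owner_map[node.id] != 0:
                    rec = self.shards[owner_map[node.id]].splits[(t, node.id)]
                    node.feature = rec.feature
                    node.bin = rec.bin
                    node.threshold = rec.threshold
            model.trees.append(merged)
        return model


class _HostParty:
    """Feature-only party: local binning, sealed histograms, owned splits."""

    def __init__(self, party: int, features: pd.DataFrame, n_bins: int):
        self.party = party
        self.feature_names = [str(c) for c in features.columns]
        self.values = features.to_numpy(dtype=np.float64)
        self.ids = [str(i) for i in features.index]
        self._pos = {i: p for p, i in enumerate(self.ids)}
        edges, self.codes = quantile_bin(self.values, n_bins)
        self.edges = {f: e for f, e in zip(self.feature_names, edges)}
        self.n_bins_per_feature = [len(e) + 1 for e in edges]
        self.shard = PartyShard(party=party, edges=dict(self.edges))
        self._sealed: SealedGradients | None = None
        self._node_ids: dict[tuple[int, int], list[str]] = {}

    def handle(self, msg: Message) -> list[Message]:
        if msg.kind == "gradients":
            self._sealed = msg.payload["sealed"]
            return []
        if msg.kind == "leaf_assignment":
            t = msg.payload["tree"]
            replies = []
            for node_id, id_list in msg.payload["nodes"].items():
                node_id = int(node_id)
                self._node_ids[(t, node_id)] = id_list
                idx = np.fromiter(
                    (self._pos[i] for i in id_list), dtype=np.intp, count=len(id_list)
                )
                sealed_hist = self._sealed.histogram(
                    self.codes, idx, self.n_bins_per_feature
                )
                features = {
                    f: {
                        "sealed": sealed_hist,
                        "count": sealed_hist.counts[k],
                        "slot": k,
                    }
                    for k, f in enumerate(self.feature_names)
                }
                replies.append(
                    Message(
                        self.party, 0, "histogram",
                        {"tree": t, "node": node_id, "features": features},
                    )
                )
            return replies
        if msg.kind == "split_broadcast":
            t, node_id = msg.payload["tree"], msg.payload["node"]
            fname, q = msg.payload["feature"], msg.payload["bin"]
            k = self.feature_names.index(fname)
            threshold = float(self.edges[fname][q])
            self.shard.splits[(t, node_id)] = SplitRecord(
                feature=fname,
                bin=q,
                threshold=threshold,
                gain=msg.payload["gain"],
                cover=msg.payload["cover"],
            )
            id_list = self._node_ids[(t, node_id)]
            idx = np.fromiter((self._pos[i] for i in id_list), dtype=np.intp)
            left_mask = self.codes[idx, k] <= q
            left_ids = [i for i, keep in zip(id_list, left_mask) if keep]
            return [
                Message(
                    self.party, 0, "split_answer",
                    {"tree": t, "node": node_id, "left_ids": left_ids},
                )
            ]
        raise ProtocolError(f"host {self.party} cannot handle kind {msg.kind!r}")


class _HostPredictor:
    """Prediction-time responder: routes sample ids through its owned splits."""

    def __init__(self, shard: PartyShard, features: pd.DataFrame):
        self.party = shard.party
        self.shard = shard
        self.features = features
        self._pos = {str(i): p for p, i in enumerate(features.index)}

    def handle(self, msg: Message) -> list[Message]:
        if msg.kind != "routing_query":
            raise ProtocolError(f"host {self.party} cannot handle kind {msg.kind!r}")
        t, node_id = msg.payload["tree"], msg.payload["node"]
        key = (t, node_id)
        if key not in self.shard.splits:
            raise ProtocolError(f"party {self.party} owns no record for node {key}")
        rec = self.shard.splits[key]
        col = self.features[rec.feature].to_numpy(dtype=np.float64)
        left_ids = [
            i for i in msg.payload["ids"] if col[self._pos[i]] < rec.threshold
        ]
        return [
            Message(
                self.party, 0, "routing_answer",
                {"tree": t, "node": node_id, "left_ids": left_ids},
            )
        ]


# ---------------------------------------------------------------------------
# Training


def run_federated_training(
    partition: VerticalPartition,
    working_labels: WorkingLabels | np.ndarray,
    config: BoostConfig | None = None,
    transport: InProcessTransport | None = None,
    backend: PlainSealingBackend | None = None,
) -> tuple[FederatedBoostedModel, MessageLog]:
    """Grow the ensemble over the guest/host protocol.

    The result is equivalent to :func:`fit_boosting` on the column-concatenated
    data under identical config and binning — same splits, gains and leaf
    weights. Every cross-party message is recorded in the returned log.
    """
    config = config or BoostConfig()
    config.validate()
    transport = transport or InProcessTransport()
    backend = backend or PlainSealingBackend()
    y = (
        working_labels.y_tilde
        if isinstance(working_labels, WorkingLabels)
        else np.asarray(working_labels)
    )
    n = partition.n_samples
    if y.shape[0] != n:
        raise ProtocolError("working labels misaligned with the partition")

    ids = [str(i) for i in partition.aligned_ids]
    pos_of = {i: p for p, i in enumerate(ids)}
    hosts = [
        _HostParty(hv.party, hv.features, config.n_bins)
        for hv in sorted(partition.hosts, key=lambda h: h.party)
    ]
    for h in hosts:
        transport.register(h.party, h.handle)

    guest_names = [str(c) for c in partition.guest.features.columns]
    if guest_names:
        guest_values = partition.guest.features.to_numpy(dtype=np.float64)
        guest_edges, guest_codes = quantile_bin(guest_values, config.n_bins)
    else:
        guest_values = np.empty((n, 0))
        guest_edges, guest_codes = [], np.empty((n, 0), dtype=np.int32)
    guest_nbins = [len(e) + 1 for e in guest_edges]

    feature_names = partition.feature_order()
    owner_of: list[int] = [0] * len(guest_names)
    local_slot: list[int] = list(range(len(guest_names)))
    for h in hosts:
        owner_of.extend([h.party] * len(h.feature_names))
        local_slot.extend(range(len(h.feature_names)))

    guest_shard = PartyShard(
        party=0, edges={f: e for f, e in zip(guest_names, guest_edges)}
    )
    model = FederatedBoostedModel(
        feature_names=feature_names,
        assignment=dict(
            partition.assignment
            or {f: owner_of[k] for k, f in enumerate(feature_names)}
        ),
        config=config,
        shards={0: guest_shard, **{h.party: h.shard for h in hosts}},
    )

    margins = np.full(n, config.base_margin, dtype=np.float64)
    ids_arr = np.array(ids, dtype=object)
    for t in range(config.n_trees):
        grads = compute_gradients(y, margins)
        sealed = backend.seal(grads)
        for h in hosts:
            transport.send(Message(0, h.party, "gradients", {"tree": t, "sealed": sealed}))
        g_root, h_root = float(grads.g.sum()), float(grads.h.sum())
        tree = Tree()
        tree.nodes.append(TreeNode(id=0, is_leaf=True, n_samples=n, cover=h_root))
        owner_map: dict[int, int] = {}
        leaf_of = np.zeros(n, dtype=np.intp)
        frontier = [(0, np.arange(n, dtype=np.intp), g_root, h_root)]
        for _depth in range(config.max_depth):
            if not frontier:
                break
            node_ids_payload = {
                node_id: ids_arr[idx].tolist() for node_id, idx, _, _ in frontier
            }
            host_hists: dict[tuple[int, int], dict] = {}
            for h in hosts:
                replies = transport.send(
                    Message(
                        0, h.party, "leaf_assignment",
                        {"tree": t, "nodes": node_ids_payload},
                    )
                )
                for r in replies:
                    host_hists[(r.sender, r.payload["node"])] = r.payload["features"]
            next_frontier = []
            for node_id, idx, g_tot, h_tot in frontier:
                hist = _assemble_histogram(
                    guest_codes, guest_nbins, grads, idx,
                    hosts, host_hists, node_id, backend,
                )
                best = find_best_split(hist, g_tot, h_tot, idx.size, config)
                if best is None:
                    continue
                owner = owner_of[best.feature]
                fname = feature_names[best.feature]
                node = tree.nodes[node_id]
                if owner == 0:
                    k = local_slot[best.feature]
                    go_left = guest_codes[idx, k] <= best.bin
                    left_idx, right_idx = idx[go_left], idx[~go_left]
                    node.feature = fname
                    node.bin = best.bin
                    node.threshold = float(guest_edges[k][best.bin])
                    guest_shard.splits[(t, node_id)] = SplitRecord(
                        feature=fname,
                        bin=best.bin,
                        threshold=node.threshold,
                        gain=best.gain,
                        cover=h_tot,
                    )
                else:
                    replies = transport.send(
                        Message(
                            0, owner, "split_broadcast",
                            {
                                "tree": t,
                                "node": node_id,
                                "feature": fname,
                                "bin": best.bin,
                                "gain": best.gain,
                                "cover": h_tot,
                            },
                        )
                    )
                    left_ids = replies[0].payload["left_ids"]
                    left_set = set(left_ids)
                    in_left = np.fromiter(
                        (ids_arr[i] in left_set for i in idx), dtype=bool, count=idx.size
                    )
                    left_idx, right_idx = idx[in_left], idx[~in_left]
                owner_map[node_id] = owner
                left = TreeNode(
                    id=len(tree.nodes), is_leaf=True,
                    n_samples=left_idx.size, cover=best.h_left,
                )
                tree.nodes.append(left)
                right = TreeNode(
                    id=len(tree.nodes), is_leaf=True,
                    n_samples=right_idx.size, cover=h_tot - best.h_left,
                )
                tree.nodes.append(right)
                node.is_leaf = False
                node.gain = best.gain
                node.left, node.right = left.id, right.id
                leaf_of[left_idx] = left.id
                leaf_of[right_idx] = right.id
                next_frontier.append((left.id, left_idx, best.g_left, best.h_left))
                next_frontier.append(
                    (right.id, right_idx, g_tot - best.g_left, h_tot - best.h_left)
                )
            frontier = next_frontier
        assign_leaf_weights(tree, leaf_of, grads, config)
        weights = np.array([nd.weight for nd in tree.nodes])
        margins += config.learning_rate * weights[leaf_of]
        model.trees.append(tree)
        model.owners.append(owner_map)
    return model, transport.log


def _assemble_histogram(
    guest_codes, guest_nbins, grads, idx, hosts, host_hists, node_id, backend
) -> Histogram:
    """Global-feature-order histogram: guest's own bins plus unsealed host bins."""
    guest_part = build_histogram(guest_codes, grads, idx, guest_nbins)
    G, H, C = list(guest_part.G), list(guest_part.H), list(guest_part.count)
    for h in hosts:
        features = host_hists[(h.party, node_id)]
        for fname in h.feature_names:
            entry = features[fname]
            opened = backend.unseal_histogram(entry["sealed"])
            k = entry["slot"]
            G.append(opened.G[k])
            H.append(opened.H[k])
            C.append(opened.count[k])
    return Histogram(G=G, H=H, count=C)


# ---------------------------------------------------------------------------
# Prediction


def federated_predict(
    model: FederatedBoostedModel,
    partition: VerticalPartition,
    transport: InProcessTransport | None = None,
) -> np.ndarray:
    """Joint prediction: guest routes; owners answer left/right on their nodes."""
    transport = transport or InProcessTransport()
    for hv in partition.hosts:
        if hv.party not in model.shards:
            raise ProtocolError(f"unknown owning party: {hv.party}")
        transport.register(
            hv.party, _HostPredictor(model.shards[hv.party], hv.features).handle
        )
    guest_feats = partition.guest.features
    ids = [str(i) for i in partition.aligned_ids]
    pos_of = {i: p for p, i in enumerate(ids)}
    ids_arr = np.array(ids, dtype=object)
    n = len(ids)
    margins = np.full(n, model.config.base_margin, dtype=np.float64)
    for t, (tree, owner_map) in enumerate(zip(model.trees, model.owners)):
        assign = np.zeros(n, dtype=np.intp)
        contrib = np.zeros(n, dtype=np.float64)
        for node in tree.nodes:
            mask = assign == node.id
            if not mask.any():
                continue
            if node.is_leaf:
                contrib[mask] = node.weight
                continue
            owner = owner_map[node.id]
            if owner == 0:
                v = guest_feats[node.feature].to_numpy(dtype=np.float64)[mask]
                assign[mask] = np.where(v < node.threshold, node.left, node.right)
            else:
                replies = transport.send(
                    Message(
                        0, owner, "routing_query",
                        {"tree": t, "node": node.id, "ids": ids_arr[mask].tolist()},
                    )
                )
                left_set = set(replies[0].payload["left_ids"])
                here = np.flatnonzero(mask)
                goes_left = np.fromiter(
                    (ids_arr[i] in left_set for i in here), dtype=bool, count=here.size
                )
                assign[here] = np.where(goes_left, node.left, node.right)
        margins += model.config.learning_rate * contrib
    m = np.clip(margins, -MARGIN_CLIP, MARGIN_CLIP)
    return 1.0 / (1.0 + np.exp(-m))


# ---------------------------------------------------------------------------
# Privacy audit


@dataclass
class Violation:
    index: int
    rule: str
    detail: str


_LABEL_KEYS = frozenset({"y", "label", "labels", "working_labels", "y_tilde", "s"})
_RAW_GRADIENT_KEYS = frozenset({"g", "h", "gradients", "grads"})
_FEATURE_VALUE_KEYS = frozenset({"values", "feature_values", "x", "threshold", "thresholds"})
_ANSWER_KEYS = frozenset({"tree", "node", "left_ids"})


def _find_keys(payload, keys: frozenset, prefix: str = "") -> list[str]:
    found = []
    if isinstance(payload, dict):
        for k, v in payload.items():
            path = f"{prefix}.{k}" if prefix else str(k)
            if str(k) in keys:
                found.append(path)
            found.extend(_find_keys(v, keys, path))
    elif isinstance(payload, (list, tuple)):
        for i, v in enumerate(payload):
            found.extend(_find_keys(v, keys, f"{prefix}[{i}]"))
    return found


def privacy_audit(
    log: MessageLog, partition: VerticalPartition | None = None
) -> list[Violation]:
    """Transcript rules of the split protocol, as data (never exceptions).

    Clean iff (a) no host-bound message carries labels, working labels or
    unsealed gradients; (b) no guest-bound message carries raw host feature
    values or host thresholds; (c) the only host→guest message kinds are
    histogram aggregates, split answers and routing answers (payloads limited to
    node ids, sample-id sets and sealed/counted aggregates).
    """
    violations: list[Violation] = []
    for i, msg in enumerate(log):
        if msg.kind not in MESSAGE_KINDS:
            violations.append(Violation(i, "off_protocol_kind", f"unknown kind {msg.kind!r}"))
            continue
        if msg.receiver != 0:  # host-bound
            if msg.kind not in GUEST_TO_HOST_KINDS:
                violations.append(
                    Violation(i, "off_protocol_kind", f"{msg.kind!r} sent to host {msg.receiver}")
                )
            for path in _find_keys(msg.payload, _LABEL_KEYS):
                violations.append(
                    Violation(i, "label_to_host", f"label-bearing field {path!r}")
                )
            if msg.kind == "gradients":
                sealed = msg.payload.get("sealed")
                if not isinstance(sealed, SealedGradients):
                    violations.append(
                        Violation(i, "unsealed_gradients", "gradients payload is not sealed")
                    )
            for path in _find_keys(msg.payload, _RAW_GRADIENT_KEYS):
                violations.append(
                    Violation(i, "unsealed_gradients", f"raw gradient field {path!r}")
                )
        else:  # guest-bound
            if msg.sender == 0:
                continue
            if msg.kind not in HOST_TO_GUEST_KINDS:
                violations.append(
                    Violation(i, "off_protocol_kind", f"{msg.kind!r} sent host→guest")
                )
                continue
            for path in _find_keys(msg.payload, _FEATURE_VALUE_KEYS):
                violations.append(
                    Violation(i, "feature_leak_to_guest", f"raw-feature field {path!r}")
                )
            if msg.kind in ("split_answer", "routing_answer"):
                extra = set(map(str, msg.payload)) - _ANSWER_KEYS
                if extra:
                    violations.append(
                        Violation(i, "schema", f"unexpected answer fields {sorted(extra)}")
                    )
            elif msg.kind == "histogram":
                extra = set(map(str, msg.payload)) - {"tree", "node", "features"}
                if extra:
                    violations.append(
                        Violation(i, "schema", f"unexpected histogram fields {sorted(extra)}")
                    )
                for fname, entry in msg.payload.get("features", {}).items():
                    if not isinstance(entry.get("sealed"), SealedHistogram):
                        violations.append(
                            Violation(
                                i, "unsealed_histogram",
                                f"histogram for {fname!r} is not sealed",
                            )
                        )
    return violations


# ---------------------------------------------------------------------------
# Estimator


class VerticalFederatedClassifier(BaseEstimator, ClassifierMixin):
    """Vertically federated gradient-boosted trees with a sklearn surface.

    ``assignment`` maps feature name → party index (0 = guest, labels); None
    keeps every feature at the guest (degenerate single-party federation).
    """

    def __init__(
        self,
        assignment: dict[str, int] | None = None,
        n_trees: int = 30,
        max_depth: int = 3,
        learning_rate: float = 0.3,
        reg_lambda: float = 1.0,
        gamma: float = 0.0,
        n_bins: int = 32,
        min_child_samples: int = 1,
        base_margin: float = 0.0,
    ):
        self.assignment = assignment
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.reg_lambda = reg_lambda
        self.gamma = gamma
        self.n_bins = n_bins
        self.min_child_samples = min_child_samples
        self.base_margin = base_margin

    def _config(self) -> BoostConfig:
        return BoostConfig(
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            reg_lambda=self.reg_lambda,
            gamma=self.gamma,
            n_bins=self.n_bins,
            min_child_samples=self.min_child_samples,
            base_margin=self.base_margin,
        )

    def _partition(self, X) -> VerticalPartition:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(
                np.asarray(X, dtype=np.float64),
                columns=[f"f{i}" for i in range(np.asarray(X).shape[1])],
            )
        table = SampleTable(features=X, s=np.zeros(len(X), dtype=np.int8))
        assignment = self.assignment or {str(c): 0 for c in X.columns}
        return vertical_split(table, assignment)

    def fit(self, X, y):
        y = np.asarray(y)
        if not np.isin(y, (0, 1)).all():
            raise DataError("labels must be binary in {0,1}")
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        partition = self._partition(X)
        labels = WorkingLabels(y_tilde=y.astype(np.int8), observed=y == 1)
        self.model_, self.log_ = run_federated_training(
            partition, labels, self._config()
        )
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        p1 = federated_predict(self.model_, self._partition(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def audit_(self) -> list[Violation]:
        check_is_fitted(self, "log_")
        return privacy_audit(self.log_)
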