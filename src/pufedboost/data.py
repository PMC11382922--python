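"""Tabular sample containers, CSV I/O, PU masking, balancing, and vertical partitioning.

The central container is :class:`SampleTable`: an id-indexed feature matrix with an
optional true binary label ``y`` and a per-sample PU flag ``s`` (``s=1`` marks a
*labeled positive*; ``s=0`` samples are unlabeled and may be of either class).
``y`` is carried for evaluation only — training code never receives it, only
:class:`WorkingLabels` derived from ``s``.

A :class:`VerticalPartition` splits a table column-wise across federated parties:
the guest (party 0) keeps the flags (and, for evaluation, ``y``); hosts hold
disjoint feature blocks and structurally cannot carry labels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Malformed input data (duplicate ids, non-numeric cells, bad labels)."""


class PartitionError(ValueError):
    """Invalid vertical feature assignment."""


class ParameterError(ValueError):
    """Out-of-range parameter."""


def _as_flag_array(values, name: str, n: int) -> np.ndarray:
    arr = np.asarray(values)
    if arr.shape != (n,):
        raise DataError(f"{name} must have length {n}, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise DataError(f"{name} must be binary in {{0,1}}")
    return arr.astype(np.int8)


@dataclass
class SampleTable:
    """Aligned sample ids, features, optional true labels y, and PU flags s."""

    features: pd.DataFrame
    s: np.ndarray
    y: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.features, pd.DataFrame):
            self.features = pd.DataFrame(self.features)
        ids = self.features.index
        if ids.has_duplicates:
            dup = ids[ids.duplicated()][0]
            raise DataError(f"duplicate sample id: {dup!r}")
        cols = self.features.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise DataError(f"duplicate feature name: {dup!r}")
        values = self.features.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise DataError("feature matrix contains non-numeric values")
        if values.size and not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise DataError(
                f"non-finite feature value at sample {ids[r]!r}, column {cols[c]!r}"
            )
        n = len(ids)
        self.s = _as_flag_array(self.s, "s", n)
        if self.y is not None:
            self.y = _as_flag_array(self.y, "y", n)
            bad = (self.s == 1) & (self.y != 1)
            if bad.any():
                raise DataError(
                    f"sample {ids[np.argmax(bad)]!r} has s=1 but y!=1 "
                    "(only positives may be flagged as labeled)"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.features.index)

    @property
    def n_samples(self) -> int:
        return len(self.features.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def subset(self, row_idx: np.ndarray) -> "SampleTable":
        return SampleTable(
            features=self.features.iloc[row_idx],
            s=self.s[row_idx],
            y=None if self.y is None else self.y[row_idx],
        )


@dataclass
class WorkingLabels:
    """Per-stage training target of the PU loop.

    ``y_tilde`` is the current surrogate label; ``observed`` is True for samples
    whose positivity is observed (s=1), False for imputed labels. Every s=1 sample
    must carry y_tilde=1 at every stage.
    """

    y_tilde: np.ndarray
    observed: np.ndarray

    def __post_init__(self) -> None:
        self.y_tilde = np.asarray(self.y_tilde, dtype=np.int8)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.y_tilde.shape != self.observed.shape:
            raise DataError("working-label arrays must be aligned")
        if not np.isin(self.y_tilde, (0, 1)).all():
            raise DataError("working labels must be binary")
        if (self.observed & (self.y_tilde != 1)).any():
            raise DataError("observed positives must have working label 1")

    @classmethod
    def from_flags(cls, s: np.ndarray) -> "WorkingLabels":
        """Stage-0 initialization: unlabeled samples treated as negative."""
        s = np.asarray(s)
        return cls(y_tilde=(s == 1).astype(np.int8), observed=s == 1)

    @property
    def n_positive(self) -> int:
        return int(self.y_tilde.sum())


@dataclass
class HostView:
    """A host party's slice: features only — the type has no label/flag slot."""

    party: int
    features: pd.DataFrame


@dataclass
class GuestView:
    party: int
    features: pd.DataFrame
    s: np.ndarray
    y: np.ndarray | None = None


@dataclass
class VerticalPartition:
    """Row-aligned per-party views of one table; party 0 (guest) holds the flags."""

    guest: GuestView
    hosts: list[HostView]
    assignment: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = list(self.guest.features.index)
        seen: set[str] = set(self.guest.features.columns)
        for hv in self.hosts:
            if list(hv.features.index) != ids:
                raise PartitionError(f"party {hv.party} rows misaligned with guest")
            overlap = seen.intersection(hv.features.columns)
            if overlap:
                raise PartitionError(f"feature {next(iter(overlap))!r} in two views")
            seen.update(hv.features.columns)

    @property
    def aligned_ids(self) -> list:
        return list(self.guest.features.index)

    @property
    def n_samples(self) -> int:
        return len(self.guest.features.index)

    @property
    def parties(self) -> list[int]:
        return [self.guest.party] + [h.party for h in self.hosts]

    def feature_order(self) -> list[str]:
        """Global feature order: guest columns, then each host's in party order."""
        names = list(self.guest.features.columns)
        for hv in sorted(self.hosts, key=lambda h: h.party):
            names.extend(hv.features.columns)
        return names

    def concat_features(self) -> pd.DataFrame:
        """Column-wise reassembly in global feature order (centralized oracle input)."""
        frames = [self.guest.features] + [
            h.features for h in sorted(self.hosts, key=lambda h: h.party)
        ]
        return pd.concat(frames, axis=1)


# ---------------------------------------------------------------------------
# CSV I/O


def load_feature_table(
    path: str | Path,
    id_col: str = "sample_id",
    label_col: str | None = None,
    flag_col: str | None = None,
) -> SampleTable:
    """Load a sample table from a headered CSV.

    Columns other than ``id_col``, ``label_col`` and ``flag_col`` are features.
    Without a flag column, ``s`` is all-zero (apply :func:`mask_positive_labels`
    downstream when ``y`` is present).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    df = pd.read_csv(path)
    for col in (id_col, label_col, flag_col):
        if col is not None and col not in df.columns:
            raise DataError(f"missing named column: {col!r}")
    ids = df[id_col]
    if ids.duplicated().any():
        raise DataError(f"duplicate sample id: {ids[ids.duplicated()].iloc[0]!r}")
    feature_cols = [c for c in df.columns if c not in {id_col, label_col, flag_col}]
    feats = df[feature_cols]
    for c in feature_cols:
        numeric = pd.to_numeric(feats[c], errors="coerce")
        bad = numeric.isna() & feats[c].notna()
        if bad.any():
            row = ids[bad].iloc[0]
            raise DataError(f"non-numeric feature cell at sample {row!r}, column {c!r}")
        if numeric.isna().any():
            row = ids[numeric.isna()].iloc[0]
            raise DataError(f"missing feature value at sample {row!r}, column {c!r}")
    features = feats.apply(pd.to_numeric).astype(float)
    features.index = pd.Index(ids.astype(str), name=id_col)
    y = None if label_col is None else df[label_col].to_numpy()
    s = np.zeros(len(df), dtype=np.int8) if flag_col is None else df[flag_col].to_numpy()
    return SampleTable(features=features, s=s, y=y)


def write_feature_table(
    table: SampleTable,
    path: str | Path,
    id_col: str = "sample_id",
    label_col: str = "y",
    flag_col: str = "s",
) -> None:
    """Write the CSV contract of :func:`load_feature_table` (comma, UTF-8, header)."""
    df = table.features.copy()
    df.insert(0, id_col, [str(i) for i in table.features.index])
    if table.y is not None:
        df[label_col] = table.y
    df[flag_col] = table.s
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Preprocessing


def mask_positive_labels(
    table: SampleTable, labeled_fraction: float, seed: int
) -> SampleTable:
    """SCAR-style masking: flag exactly round(fraction x #positives) positives.

    Uses round-half-to-even, so 20% of 665 positives flags 133. ``y`` is retained
    for evaluation; all unflagged samples get s=0.
    """
    if not 0.0 < labeled_fraction <= 1.0:
        raise ParameterError(f"labeled_fraction must be in (0,1], got {labeled_fraction}")
    if table.y is None:
        raise DataError("masking requires true labels y")
    pos_idx = np.flatnonzero(table.y == 1)
    if pos_idx.size == 0:
        raise DataError("masking requires at least one positive sample")
    n_flag = int(round(labeled_fraction * pos_idx.size))  # round-half-to-even
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pos_idx, size=n_flag, replace=False)
    s = np.zeros(table.n_samples, dtype=np.int8)
    s[chosen] = 1
    return SampleTable(features=table.features, s=s, y=table.y)


def undersample_balance(table: SampleTable, seed: int) -> SampleTable:
    """Random undersampling of the majority class down to the minority count.

    Retained rows keep their original relative order, so the result is
    reproducible independent of sort stability.
    """
    if table.y is None:
        raise DataError("undersampling requires true labels y")
    pos = np.flatnonzero(table.y == 1)
    neg = np.flatnonzero(table.y == 0)
    if pos.size == 0 or neg.size == 0:
        raise DataError("undersampling requires both classes present")
    rng = np.random.default_rng(seed)
    if pos.size > neg.size:
        keep_major = rng.choice(pos, size=neg.size, replace=False)
        keep = np.concatenate([keep_major, neg])
    elif neg.size > pos.size:
        keep_major = rng.choice(neg, size=pos.size, replace=False)
        keep = np.concatenate([pos, keep_major])
    else:
        return table
    keep.sort()
    return table.subset(keep)


def vertical_split(
    table: SampleTable, assignment: Mapping[str, int]
) -> VerticalPartition:
    """Partition a table column-wise by the feature→party assignment map.

    Party 0 (guest) receives its features plus the flags ``s`` (and ``y`` if
    present); each host receives only its feature block.
    """
    names = table.feature_names
    missing = [f for f in names if f not in assignment]
    if missing:
        raise PartitionError(f"unassigned feature: {missing[0]!r}")
    extra = [f for f in assignment if f not in names]
    if extra:
        raise PartitionError(f"assignment names unknown feature: {extra[0]!r}")
    # the guest always exists, possibly with zero features (labels only)
    parties = sorted(set(assignment.values()) | {0})
    by_party: dict[int, list[str]] = {p: [] for p in parties}
    for f in names:  # preserve source column order within each party
        by_party[assignment[f]].append(f)
    if not by_party[0]:
        warnings.warn("guest holds no features (labels only)", stacklevel=2)
    guest = GuestView(
        party=0, features=table.features[by_party[0]], s=table.s, y=table.y
    )
    hosts = [
        HostView(party=p, features=table.features[by_party[p]])
        for p in parties
        if p != 0
    ]
    return VerticalPartition(guest=guest, hosts=hosts, assignment=dict(assignment))


def split_parties_evenly(feature_names: Sequence[str], n_parties: int) -> dict[str, int]:
    """Contiguous, near-even feature→party assignment (guest first)."""
    if n_parties < 1:
        raise ParameterError("n_parties must be >= 1")
    names = list(feature_names)
    blocks = np.array_split(np.arange(len(names)), n_parties)
    out: dict[str, int] = {}
    for p, block in enumerate(blocks):
        for i in block:
            out[names[i]] = p
    return out


def save_partition(partition: VerticalPartition, directory: str | Path) -> None:
    """One CSV per party plus a JSON manifest (id order, assignment, roles)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    guest_df = partition.guest.features.copy()
    guest_df.insert(0, "sample_id", [str(i) for i in guest_df.index])
    guest_df["s"] = partition.guest.s
    if partition.guest.y is not None:
        guest_df["y"] = partition.guest.y
    guest_df.to_csv(directory / "party_0.csv", index=False)
    for hv in partition.hosts:
        df = hv.features.copy()
        df.insert(0, "sample_id", [str(i) for i in df.index])
        df.to_csv(directory / f"party_{hv.party}.csv", index=False)
    manifest = {
        "aligned_ids": [str(i) for i in partition.aligned_ids],
        "assignment": partition.assignment,
        "roles": {"0": "guest", **{str(h.party): "host" for h in partition.hosts}},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
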