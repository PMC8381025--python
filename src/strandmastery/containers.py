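"""Core data containers: response matrices, Q-matrices, mastery and ability arrays.

All containers are thin wrappers over NumPy arrays that enforce the
invariants of the mastery-classification workflow (binary, complete data;
consistent dimensions) and provide lossless CSV round-trips in a common
dialect: one observation row per person (or item), an identifier in the
first column, and variable names in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "ResponseMatrix",
    "AbilityMatrix",
    "MasteryMatrix",
    "as_values",
]


def as_values(x) -> np.ndarray:
    """Return the underlying array of a container, or the array itself."""
    return np.asarray(getattr(x, "values", getattr(x, "entries", x)))


def _check_binary(values: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"{what} must be 2-dimensional, got shape {arr.shape}")
    if np.isnan(arr.astype(float)).any():
        raise ValueError(f"{what} contains missing values; complete data required")
    if not np.isin(arr, (0, 1)).all():
        bad = np.argwhere(~np.isin(arr, (0, 1)))[0]
        raise ValueError(
            f"{what} must be binary; non-{{0,1}} entry at row {bad[0]}, column {bad[1]}"
        )
    return arr.astype(np.int8)


@dataclass
class QMatrix:
    """Items x attributes incidence matrix: q_ik = 1 if item i requires attribute k.

    A *simple structure* Q-matrix has exactly one attribute per item, the
    setting in which CTT subscores and per-strand Rasch fits are defined.
    """

    entries: np.ndarray
    attribute_names: list[str] = field(default=None)
    item_names: list[str] = field(default=None)

    def __post_init__(self):
        self.entries = _check_binary(self.entries, "Q-matrix")
        n_items, n_attr = self.entries.shape
        if (self.entries.sum(axis=1) == 0).any():
            bad = int(np.argwhere(self.entries.sum(axis=1) == 0)[0][0])
            raise ValueError(f"Q-matrix row {bad} has no attribute assigned")
        if self.attribute_names is None:
            self.attribute_names = [f"A{k + 1}" for k in range(n_attr)]
        if self.item_names is None:
            self.item_names = [f"item{i + 1}" for i in range(n_items)]
        if len(self.attribute_names) != n_attr or len(self.item_names) != n_items:
            raise ValueError("Q-matrix label lengths do not match entry dimensions")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @property
    def is_simple_structure(self) -> bool:
        return bool((self.entries.sum(axis=1) == 1).all())

    def item_attribute(self) -> np.ndarray:
        """Per-item attribute index k(i); requires simple structure."""
        if not self.is_simple_structure:
            raise ValueError("item_attribute is defined for simple-structure Q-matrices only")
        return self.entries.argmax(axis=1)

    def attribute_items(self, k: int) -> np.ndarray:
        """Indices of the items loading attribute k."""
        return np.flatnonzero(self.entries[:, k] == 1)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.entries, index=self.item_names, columns=self.attribute_names)
        df.index.name = "item"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            entries=df.to_numpy(),
            attribute_names=[str(c) for c in df.columns],
            item_names=[str(i) for i in df.index],
        )


@dataclass
class ResponseMatrix:
    """Persons x items binary scored responses X_ij (1 = correct)."""

    values: np.ndarray
    person_ids: list[str] = field(default=None)
    item_names: list[str] = field(default=None)

    def __post_init__(self):
        self.values = _check_binary(self.values, "response matrix")
        n_persons, n_items = self.values.shape
        if self.person_ids is None:
            self.person_ids = [f"p{j + 1}" for j in range(n_persons)]
        if self.item_names is None:
            self.item_names = [f"item{i + 1}" for i in range(n_items)]
        if len(self.person_ids) != n_persons or len(self.item_names) != n_items:
            raise ValueError("response matrix label lengths do not match dimensions")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def subset_items(self, idx: np.ndarray) -> "ResponseMatrix":
        idx = np.asarray(idx)
        return ResponseMatrix(
            values=self.values[:, idx],
            person_ids=list(self.person_ids),
            item_names=[self.item_names[i] for i in idx],
        )

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.person_ids, columns=self.item_names)
        df.index.name = "person"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        df = pd.read_csv(path, index_col=0)
        if df.isna().any().any():
            rows = df.index[df.isna().any(axis=1)].tolist()[:5]
            raise ValueError(f"response CSV has missing cells (e.g., persons {rows})")
        return cls(
            values=df.to_numpy(),
            person_ids=[str(i) for i in df.index],
            item_names=[str(c) for c in df.columns],
        )


@dataclass
class AbilityMatrix:
    """Persons x attributes latent abilities theta_jk on the logit scale."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ability matrix must be 2-dimensional")
        if not np.isfinite(self.values).all():
            raise ValueError("ability matrix must be finite")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, attribute_names=None) -> None:
        cols = attribute_names or [f"A{k + 1}" for k in range(self.n_attributes)]
        df = pd.DataFrame(self.values, columns=cols)
        df.index = [f"p{j + 1}" for j in range(self.n_persons)]
        df.index.name = "person"
        df.to_csv(path)


@dataclass
class MasteryMatrix:
    """Persons x attributes binary mastery states alpha_jk (true or estimated)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = _check_binary(self.values, "mastery matrix")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path, attribute_names=None) -> None:
        cols = attribute_names or [f"A{k + 1}" for k in range(self.values.shape[1])]
        df = pd.DataFrame(self.values, columns=cols)
        df.index = [f"p{j + 1}" for j in range(self.values.shape[0])]
        df.index.name = "person"
        df.to_csv(path)
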