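"""Selection-dataset container and CSV serialization.

A selection dataset holds, per record, outcome covariates ``x`` (p columns),
selection covariates ``v`` (q columns), a binary selection indicator ``s``,
and the outcome ``y`` which is observed only when ``s == 1``.  All in-package
code assumes *selected-first* ordering (records with ``s == 1`` come before
records with ``s == 0``); the constructors enforce it and keep the index map
back to the original order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SelectionDataset", "read_dataset_csv", "write_dataset_csv"]


@dataclass
class SelectionDataset:
    """Partially observed regression data in selected-first order.

    Attributes
    ----------
    X : (n, p) ndarray
        Outcome-equation covariates.
    V : (n, q) ndarray
        Selection-equation covariates (a column of ones for an
        intercept-only selection equation).
    s : (n,) int ndarray
        Selection indicators, 1 for observed outcomes.
    y : (n,) float ndarray
        Outcomes; NaN where ``s == 0``.
    order : (n,) int ndarray
        Positions of the rows in the originally supplied ordering.
    """

    X: np.ndarray
    V: np.ndarray
    s: np.ndarray
    y: np.ndarray
    order: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] == 1 and self.X.shape[1] > 1 and len(np.asarray(self.s)) > 1:
            self.X = self.X.T
        self.V = np.atleast_2d(np.asarray(self.V, dtype=float))
        if self.V.shape[0] == 1 and self.V.shape[1] > 1 and len(np.asarray(self.s)) > 1:
            self.V = self.V.T
        self.s = np.asarray(self.s, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        n = self.s.shape[0]
        if self.X.shape[0] != n or self.V.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("X, V, s and y must have the same number of rows")
        if not np.isin(self.s, (0, 1)).all():
            raise ValueError("selection indicator s must be binary")
        if np.isnan(self.y[self.s == 1]).any():
            raise ValueError("records with s=1 must have an observed outcome y")
        if self.order is None:
            self.order = np.arange(n)
        else:
            self.order = np.asarray(self.order, dtype=int)
        if not self._selected_first():
            raise ValueError(
                "rows must be in selected-first order; use SelectionDataset.from_arrays"
            )

    def _selected_first(self) -> bool:
        n1 = int(self.s.sum())
        return bool((self.s[:n1] == 1).all())

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_arrays(cls, X, V, s, y) -> "SelectionDataset":
        """Build a dataset from arrays in arbitrary row order."""
        s = np.asarray(s, dtype=int)
        idx = np.argsort(1 - s, kind="stable")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != s.shape[0]:
            X = X.T
        V = np.atleast_2d(np.asarray(V, dtype=float))
        if V.shape[0] != s.shape[0]:
            V = V.T
        y = np.asarray(y, dtype=float)
        return cls(X=X[idx], V=V[idx], s=s[idx], y=y[idx], order=idx)

    # -- views -----------------------------------------------------------

    @property
    def n(self) -> int:
        return self.s.shape[0]

    @property
    def n1(self) -> int:
        return int(self.s.sum())

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.V.shape[1]

    @property
    def X1(self) -> np.ndarray:
        """Covariates of the selected records."""
        return self.X[: self.n1]

    @property
    def X2(self) -> np.ndarray:
        """Covariates of the unselected records."""
        return self.X[self.n1:]

    @property
    def V1(self) -> np.ndarray:
        return self.V[: self.n1]

    @property
    def y1(self) -> np.ndarray:
        """Observed outcomes (selected records only)."""
        return self.y[: self.n1]

    def selected_only(self) -> "SelectionDataset":
        """The fully observed sub-dataset (used by the GPR baseline)."""
        n1 = self.n1
        return SelectionDataset(
            X=self.X[:n1], V=self.V[:n1], s=self.s[:n1], y=self.y[:n1],
            order=np.arange(n1),
        )

    # -- serialization ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": self.X[:, j] for j in range(self.p)}
        cols.update({f"v{j + 1}": self.V[:, j] for j in range(self.q)})
        cols["s"] = self.s
        cols["y"] = self.y
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SelectionDataset":
        xcols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
        vcols = sorted((c for c in df.columns if c.startswith("v")), key=lambda c: int(c[1:]))
        if not xcols or not vcols or "s" not in df or "y" not in df:
            raise ValueError("dataset CSV must have columns x1..xp, v1..vq, s, y")
        s = df["s"].to_numpy()
        if not np.isin(s, (0, 1)).all():
            raise ValueError("column s must be binary")
        return cls.from_arrays(
            X=df[xcols].to_numpy(dtype=float),
            V=df[vcols].to_numpy(dtype=float),
            s=s.astype(int),
            y=df["y"].to_numpy(dtype=float),
        )

    @classmethod
    def read_csv(cls, path) -> "SelectionDataset":
        return cls.from_frame(pd.read_csv(path))


def read_dataset_csv(path) -> SelectionDataset:
    return SelectionDataset.read_csv(path)


def write_dataset_csv(ds: SelectionDataset, path) -> None:
    ds.to_csv(path)
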