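"""Gower dissimilarity for mixed binary/numeric consultation records.

The pairwise dissimilarity is the (weighted) mean of per-variable
contributions: 0/1 mismatch for binary or categorical variables, absolute
difference scaled by the cohort range for numeric ones.  Variables missing
on either record of a pair are skipped and the mean renormalized over the
remaining weight, so the result always lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["DissimilarityMatrix", "gower_dissimilarity"]


@dataclass
class DissimilarityMatrix:
    """Symmetric n x n dissimilarities in [0, 1] with aligned patient ids."""

    values: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} ids")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValueError("dissimilarity matrix has a nonzero diagonal")
        if np.nanmin(self.values) < -1e-12 or np.nanmax(self.values) > 1 + 1e-12:
            raise ValueError("dissimilarities must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)


def gower_dissimilarity(
    cohort: Cohort | pd.DataFrame,
    feature_spec: dict[str, str] | None = None,
    weights: dict[str, float] | None = None,
) -> DissimilarityMatrix:
    """Compute the Gower dissimilarity matrix over the clustering variables.

    Parameters
    ----------
    cohort:
        A :class:`~vioscales.cohort.Cohort` (its ``feature_spec`` is used
        unless one is passed explicitly) or a bare data frame.
    feature_spec:
        Variable name -> ``"binary" | "categorical" | "numeric"``.
    weights:
        Optional per-variable weights (default: equal weights).

    Raises
    ------
    ValueError
        If a numeric variable has zero range, or a pair of records shares no
        observed variable (the error names the pair).
    """
    if isinstance(cohort, Cohort):
        df = cohort.df
        if feature_spec is None:
            feature_spec = cohort.feature_spec
        ids = df["patient_id"].to_numpy()
    else:
        df = cohort
        ids = (
            df["patient_id"].to_numpy()
            if "patient_id" in df.columns
            else np.arange(len(df))
        )
    if not feature_spec:
        raise ValueError("feature_spec is empty: no clustering variables")
    for var in feature_spec:
        if var not in df.columns:
            raise ValueError(f"clustering variable {var!r} absent from the cohort")

    n = len(df)
    num = np.zeros((n, n))
    den_scalar = 0.0           # weight of fully-observed variables
    den_matrix = None          # per-pair weight of partially-observed ones
    for var, kind in feature_spec.items():
        w = 1.0 if weights is None else float(weights.get(var, 1.0))
        if w == 0.0:
            continue
        col = df[var]
        present = col.notna().to_numpy()
        complete = bool(present.all())
        if kind == "numeric":
            x = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
            finite = x[present]
            rng = finite.max() - finite.min() if len(finite) else 0.0
            if rng == 0.0:
                raise ValueError(f"numeric variable {var!r} has zero range")
            contrib = np.abs(x[:, None] - x[None, :]) / rng
        elif kind in ("binary", "categorical"):
            x = col.to_numpy()
            contrib = (x[:, None] != x[None, :]).astype(float)
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        if complete:
            den_scalar += w
            num += w * contrib
        else:
            valid = np.outer(present, present)
            if den_matrix is None:
                den_matrix = np.zeros((n, n))
            den_matrix += w * valid
            num += w * np.where(valid, np.nan_to_num(contrib), 0.0)

    den = den_scalar if den_matrix is None else den_matrix + den_scalar
    if den_matrix is not None and np.any(den == 0):
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(
            f"records {ids[i]!r} and {ids[j]!r} share no observed clustering variable"
        )
    if den_matrix is None and den_scalar == 0.0:
        raise ValueError("no clustering variables with positive weight")
    values = num / den
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2.0  # kill float asymmetry
    return DissimilarityMatrix(values=values, ids=ids)
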