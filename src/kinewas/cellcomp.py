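"""Reference-based blood cell-type deconvolution.

Bulk peripheral-blood methylation is a mixture of cell-type-specific profiles.
Given a reference matrix of mean beta values at discriminating probes for six
leukocyte types (monocytes, granulocytes, CD8+ T, CD4+ T, NK, B), each sample's
proportions are recovered by non-negative least squares on the shared probes,
then rescaled to sum to one. Five of the six proportions (dropping one to avoid
the sum-to-one collinearity, granulocytes by default as the largest fraction)
enter the association models as fixed-effect covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CELL_TYPES",
    "CellTypeReference",
    "estimate_cell_proportions",
    "covariate_columns",
]

CELL_TYPES = ("monocytes", "granulocytes", "CD8T", "CD4T", "NK", "B")

MIN_PROBE_OVERLAP = 6


@dataclass
class CellTypeReference:
    """Probe-by-cell-type mean beta matrix for the six blood cell types."""

    mean_beta: pd.DataFrame  # index: probe ids, columns: cell types

    def __post_init__(self):
        missing = set(CELL_TYPES) - set(self.mean_beta.columns)
        if missing:
            raise ValueError(f"reference missing cell types: {sorted(missing)}")
        if self.mean_beta.shape[0] < 1:
            raise ValueError("reference needs at least one probe")
        self.mean_beta = self.mean_beta[list(CELL_TYPES)]

    @property
    def probe_ids(self) -> pd.Index:
        return self.mean_beta.index

    @classmethod
    def read_tsv(cls, path) -> "CellTypeReference":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df)

    def write_tsv(self, path) -> None:
        self.mean_beta.to_csv(path, sep="\t", index_label="probe_id")


def estimate_cell_proportions(
    beta: pd.DataFrame, ref: CellTypeReference
) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions from a beta matrix.

    Solves ``min ||R w - b||`` subject to ``w >= 0`` over the probes shared
    between matrix and reference, then rescales each sample's weights to sum
    to 1. Returns a sample-by-cell-type DataFrame.
    """
    shared = beta.index.intersection(ref.probe_ids, sort=False)
    if len(shared) < MIN_PROBE_OVERLAP:
        raise ValueError(
            f"only {len(shared)} probes shared with the cell-type reference "
            f"(need >= {MIN_PROBE_OVERLAP})"
        )
    R = ref.mean_beta.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(R) < R.shape[1]:
        warnings.warn(
            "cell-type reference columns are collinear; falling back to "
            "pseudo-inverse least squares with clipping",
            stacklevel=2,
        )
        W = np.clip(np.linalg.pinv(R) @ beta.loc[shared].to_numpy(float), 0.0, None).T
    else:
        B = beta.loc[shared].to_numpy(float)
        W = np.empty((beta.shape[1], len(CELL_TYPES)))
        for s in range(B.shape[1]):
            W[s], _ = nnls(R, B[:, s])
    totals = W.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("degenerate fit: all-zero proportions for some sample")
    W = W / totals[:, None]
    return pd.DataFrame(W, index=beta.columns, columns=list(CELL_TYPES))


def covariate_columns(props: pd.DataFrame, drop: str = "granulocytes") -> pd.DataFrame:
    """Five-of-six covariate table: drop one cell type to break collinearity."""
    if drop not in props.columns:
        raise ValueError(
            f"unknown cell type {drop!r}; expected one of {sorted(props.columns)}"
        )
    return props.drop(columns=[drop])
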