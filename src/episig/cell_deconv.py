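"""Reference-based blood cell-type deconvolution.

Whole-blood methylation is a mixture of cell-type-specific profiles, so
case/control differences in cell composition confound differential
methylation. Given a reference panel of deconvolution CpGs profiled in
FACS-sorted leukocyte populations (default six types: CD4T, CD8T, NK,
B cells, monocytes, neutrophils), each sample's composition is estimated
by constrained least squares on the simplex:

    minimize  || beta_s - R pi ||^2   subject to  pi >= 0, sum(pi) = 1

The estimates are used downstream as covariates; one cell type (by
convention the dominant one, neutrophils) is dropped from the covariate
block to avoid the sum-to-one collinearity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import BetaMatrix, EpisigError

DEFAULT_CELL_TYPES = ("CD4T", "CD8T", "NK", "Bcell", "Mono", "Neu")

# Weight on the sum-to-one row in the augmented NNLS system. Large enough
# that the equality constraint is met to ~1e-8 before renormalization.
_SUM_PENALTY = 1e4


@dataclass
class CellReference:
    """Deconvolution CpGs x cell types reference beta panel."""

    betas: pd.DataFrame  # index: CpG ids, columns: cell types

    def __post_init__(self) -> None:
        if self.betas.shape[1] < 2:
            raise EpisigError("cell reference needs >= 2 cell types")
        if self.betas.index.has_duplicates:
            raise EpisigError("duplicate CpGs in cell reference")
        arr = self.betas.to_numpy(dtype=float)
        if np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1:
            raise EpisigError("reference betas must be in [0, 1] with no missing")

    @property
    def cell_types(self) -> list[str]:
        return list(self.betas.columns)


def read_cell_reference(path: str | Path) -> CellReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CellReference(df)


def write_cell_reference(ref: CellReference, path: str | Path) -> None:
    ref.betas.to_csv(path, sep="\t", index_label="cpg_id")


def estimate_cell_proportions(beta: BetaMatrix, ref: CellReference) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions (samples x cell types).

    Solves the simplex-constrained least-squares problem per sample via
    non-negative least squares on a system augmented with a heavily
    weighted sum-to-one row, then renormalizes exactly. Deterministic.
    Reference CpGs missing from the beta matrix are dropped; at least as
    many overlapping CpGs as cell types are required.
    """
    shared = [c for c in ref.betas.index if c in beta.values.index]
    k = len(ref.cell_types)
    if len(shared) < k:
        raise EpisigError(
            f"only {len(shared)} reference CpGs overlap the beta matrix; "
            f"need at least {k}"
        )
    R = ref.betas.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < k:
        raise EpisigError("rank-deficient cell reference panel")
    out = np.empty((beta.shape[1], k))
    B = beta.values.loc[shared].to_numpy(dtype=float)
    for j in range(beta.shape[1]):
        y = B[:, j]
        ok = ~np.isnan(y)
        if ok.sum() < k:
            raise EpisigError(
                f"sample {beta.sample_ids[j]!r}: too few non-missing "
                "reference CpGs"
            )
        a = np.vstack([R[ok], _SUM_PENALTY * np.ones((1, k))])
        b = np.concatenate([y[ok], [_SUM_PENALTY]])
        pi, _ = nnls(a, b)
        total = pi.sum()
        if total <= 0:
            raise EpisigError(f"degenerate fit for sample {beta.sample_ids[j]!r}")
        out[j] = pi / total
    return pd.DataFrame(out, index=beta.sample_ids, columns=ref.cell_types)


def covariate_block(props: pd.DataFrame, excluded_cell_type: str = "Neu") -> pd.DataFrame:
    """Drop one cell type from the proportion table for use as covariates.

    Proportions sum to one, so the full block is collinear with the
    intercept; excluding the dominant type (neutrophils by default)
    leaves the remaining columns as free composition covariates.
    """
    if excluded_cell_type not in props.columns:
        raise EpisigError(
            f"cell type {excluded_cell_type!r} not in proportions "
            f"(have {list(props.columns)})"
        )
    return props.drop(columns=[excluded_cell_type])
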