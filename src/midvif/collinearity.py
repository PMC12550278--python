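"""Collinearity diagnostics: contrast efficiency, traditional VIF, and the
contrast-based VIF (cVIF).

For a design X and contrast c, the contrast variance is
``Var(c beta-hat) = sigma^2 * c (X'X)^-1 c'`` and *efficiency* is its
reciprocal factor ``1 / (c (X'X)^-1 c')``.

The *traditional* VIF (tVIF) of one regressor is the ratio of its parameter
variance in the full model to that in a model containing only that regressor
(plus intercept).  tVIF only sees regressor correlations: an orthogonalizing
reparameterization can drive every tVIF to 1 while the variance of the
contrast of scientific interest is unchanged.

The *contrast* VIF (cVIF) is parameterization-invariant: expressed in the
condition basis (one column per condition signal, nuisance residualized
out), it compares the actual contrast variance factor against that of an
ideal reference design with the same per-condition signal energy but no
cross-condition overlap (a diagonal Gram matrix):

    cVIF(c) = [c (X'X)^-1 c'] / [sum_j c_j^2 / (X'X)_jj]

For an elementary contrast on a centered, residualized design this reduces
to the tVIF of that column.  Values above 5 conventionally warrant scrutiny
of the affected contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import Contrast, DesignMatrix

__all__ = [
    "SingularDesignError",
    "efficiency",
    "tvif",
    "map_to_condition_basis",
    "cvif",
    "collinearity_report",
    "CollinearityReport",
]

#: smallest-to-largest singular value ratio below which a design is singular
RANK_RTOL = 1e-10
CVIF_FLAG_THRESHOLD = 5.0


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (names the dependent columns)."""


def _check_rank(values: np.ndarray, names: list[str]) -> None:
    if values.shape[1] == 0:
        raise ValueError("design has no columns")
    s, vt = np.linalg.svd(values, compute_uv=True)[1:]
    if s[-1] <= RANK_RTOL * s[0]:
        null = vt[-1]
        involved = [n for n, w in zip(names, null) if abs(w) > 1e-6]
        raise SingularDesignError(
            f"design is rank deficient; dependent columns: {involved}"
        )


def _gram_inverse(design: DesignMatrix) -> np.ndarray:
    _check_rank(design.values, design.column_names)
    return np.linalg.inv(design.values.T @ design.values)


def efficiency(design: DesignMatrix, contrast: Contrast) -> float:
    """Contrast efficiency 1 / (c (X'X)^-1 c') on the full design."""
    ginv = _gram_inverse(design)
    c = np.asarray(contrast.weights, dtype=float)
    if c.shape != (design.values.shape[1],):
        raise ValueError("contrast length does not match design columns")
    return float(1.0 / (c @ ginv @ c))


def tvif(design: DesignMatrix, column: str) -> float:
    """Traditional VIF of one task column.

    Ratio of the parameter variance in the full model to that in the
    reduced model with only this column plus an intercept, which equals
    ``[(X'X)^-1]_jj * (x~' x~)`` with ``x~`` the mean-centered column.
    """
    j = design.index(column)
    if design.column_roles[j] not in ("task", "derivative"):
        raise ValueError(f"{column!r} is a {design.column_roles[j]} column, not task")
    ginv = _gram_inverse(design)
    x = design.values[:, j]
    x_centered = x - x.mean()
    return float(ginv[j, j] * (x_centered @ x_centered))


def map_to_condition_basis(
    design_model: DesignMatrix,
    transform: np.ndarray,
    c_model: Contrast,
) -> tuple[DesignMatrix, Contrast]:
    """Undo a task-column reparameterization.

    If the model's task columns are ``X_cond @ T`` for an invertible T, this
    returns the condition-basis design (task columns ``X_cond``, nuisance
    untouched) and the contrast expressing the same estimand, so that
    ``c (X'X)^-1 c'`` is preserved exactly.
    """
    transform = np.asarray(transform, dtype=float)
    task_idx = [i for i, r in enumerate(design_model.column_roles)
                if r in ("task", "derivative")]
    k = len(task_idx)
    if transform.shape != (k, k):
        raise ValueError(f"transform must be {k}x{k} for {k} task columns")
    s = np.linalg.svd(transform, compute_uv=False)
    if s[-1] <= RANK_RTOL * s[0]:
        raise np.linalg.LinAlgError("transform is singular")
    tinv = np.linalg.inv(transform)

    values = design_model.values.copy()
    values[:, task_idx] = values[:, task_idx] @ tinv
    weights = np.asarray(c_model.weights, dtype=float).copy()
    weights[task_idx] = weights[task_idx] @ tinv

    names = list(design_model.column_names)
    for rank, j in enumerate(task_idx, start=1):
        names[j] = f"cond_{rank}"
    design_cond = DesignMatrix(
        values=values,
        frame_times=design_model.frame_times,
        column_names=names,
        column_roles=list(design_model.column_roles),
        tr=design_model.tr,
        dropped=list(design_model.dropped),
    )
    return design_cond, Contrast(name=c_model.name, weights=weights,
                                 starred=c_model.starred)


def _residualized_task(design: DesignMatrix) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Task columns residualized against intercept + nuisance, plus the task
    part of the contrast support (indices)."""
    task_idx = np.array([i for i, r in enumerate(design.column_roles)
                         if r in ("task", "derivative")], dtype=int)
    nuis_idx = [i for i, r in enumerate(design.column_roles)
                if r in ("nuisance", "intercept")]
    x = design.values[:, task_idx]
    if nuis_idx:
        z = design.values[:, nuis_idx]
        beta, *_ = np.linalg.lstsq(z, x, rcond=None)
        x = x - z @ beta
    names = [design.column_names[i] for i in task_idx]
    return x, names, task_idx


def cvif(design_cond: DesignMatrix, contrast: Contrast) -> float:
    """Contrast VIF on a condition-basis design.

    Task columns are residualized against intercept and nuisance, then the
    actual contrast variance factor ``c (X'X)^-1 c'`` is divided by the
    factor in an ideal zero-overlap reference with the same per-condition
    signal energy, ``sum_j c_j^2 / (X'X)_jj``.
    """
    xr, names, task_idx = _residualized_task(design_cond)
    c = np.asarray(contrast.weights, dtype=float)
    if c.shape == (design_cond.values.shape[1],):
        if np.any(np.delete(c, task_idx) != 0):
            raise ValueError("cvif contrast must have zero weights on nuisance columns")
        c = c[task_idx]
    elif c.shape != (len(task_idx),):
        raise ValueError("contrast length matches neither the design nor its task part")
    if not np.any(c != 0):
        raise ValueError("all-zero contrast")
    _check_rank(xr, names)
    gram = xr.T @ xr
    ginv = np.linalg.inv(gram)
    actual = c @ ginv @ c
    ideal = np.sum(c ** 2 / np.diag(gram))
    return float(actual / ideal)


@dataclass
class CollinearityReport:
    """Per-contrast efficiency and cVIF plus per-column tVIFs, with flags at
    the conventional cVIF > 5 threshold."""

    contrast_table: pd.DataFrame
    column_table: pd.DataFrame
    flag_threshold: float = CVIF_FLAG_THRESHOLD

    def flagged(self) -> list[str]:
        if self.contrast_table.empty:
            return []
        sel = self.contrast_table["cvif"] > self.flag_threshold
        return list(self.contrast_table.loc[sel, "contrast"])

    def to_csv(self, contrast_path, column_path=None) -> None:
        self.contrast_table.to_csv(contrast_path, index=False)
        if column_path is not None:
            self.column_table.to_csv(column_path, index=False)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "contrasts": self.contrast_table.to_dict(orient="records"),
                "columns": self.column_table.to_dict(orient="records"),
                "flag_threshold": self.flag_threshold,
            },
            indent=2,
        )


def collinearity_report(
    design: DesignMatrix,
    contrasts: list[Contrast] | None = None,
    flag_threshold: float = CVIF_FLAG_THRESHOLD,
) -> CollinearityReport:
    """Efficiency, tVIF, and cVIF for a (condition-basis) design."""
    contrasts = contrasts or []
    rows = []
    for c in contrasts:
        val = cvif(design, c)
        rows.append(
            {
                "contrast": c.name,
                "efficiency": efficiency(design, c),
                "cvif": val,
                "flag": val > flag_threshold,
            }
        )
    col_rows = [
        {"column": name, "tvif": tvif(design, name)} for name in design.task_columns
    ]
    return CollinearityReport(
        contrast_table=pd.DataFrame(rows, columns=["contrast", "efficiency", "cvif", "flag"]),
        column_table=pd.DataFrame(col_rows, columns=["column", "tvif"]),
        flag_threshold=flag_threshold,
    )
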