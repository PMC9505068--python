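"""Group comparison and ordination of pharmacokinetic parameter tables.

Two-group comparisons use the classical equal-variance (pooled) Student
t-test with df = n_x + n_y - 2, the convention of the study design this
package serves; no multiplicity correction is applied across parameters.
PCA runs on z-scored columns because NCA parameters span several orders
of magnitude; component signs are fixed deterministically (the
largest-magnitude loading of each component is made positive) so score
plots are reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .nca import PARAM_COLUMNS

__all__ = ["PCAResult", "pooled_t_test", "group_summary", "pca_scores"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # subjects x components
    loadings: pd.DataFrame  # parameters x components
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]


def pooled_t_test(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, float]:
    """Two-sided equal-variance Student t-test.

    Returns ``(t, df, p)``. When the pooled variance is zero the test is
    degenerate: equal means give (0, df, 1); unequal means are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    df = int(x.size + y.size - 2)
    sx2 = float(x.var(ddof=1))
    sy2 = float(y.var(ddof=1))
    if sx2 == 0 and sy2 == 0:
        if math.isclose(float(x.mean()), float(y.mean()), rel_tol=0, abs_tol=0):
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)


def group_summary(
    matrix: pd.DataFrame,
    pair: tuple[str, str],
    parameters: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-parameter mean, sample SD per group and the pooled-t p-value
    for the designated group pair.

    ``matrix`` must carry a ``group`` column plus numeric parameter
    columns (default: the 14 NCA parameters present in the table).
    """
    if "group" not in matrix.columns:
        raise ValueError("matrix must have a 'group' column")
    if parameters is None:
        parameters = [c for c in PARAM_COLUMNS if c in matrix.columns]
        if not parameters:
            parameters = [
                c for c in matrix.columns
                if c not in ("subject", "group")
                and pd.api.types.is_numeric_dtype(matrix[c])
            ]
    g1, g2 = pair
    a = matrix.loc[matrix["group"] == g1, list(parameters)]
    b = matrix.loc[matrix["group"] == g2, list(parameters)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"groups {pair} need at least 2 subjects each")
    rows = []
    for param in parameters:
        t, df, p = pooled_t_test(a[param].to_numpy(), b[param].to_numpy())
        rows.append(
            {
                "parameter": param,
                f"mean_{g1}": float(a[param].mean()),
                f"sd_{g1}": float(a[param].std(ddof=1)),
                f"mean_{g2}": float(b[param].mean()),
                f"sd_{g2}": float(b[param].std(ddof=1)),
                "t": t,
                "df": df,
                "p": p,
                "significant": bool(p < alpha),
            }
        )
    out = pd.DataFrame(rows).set_index("parameter")
    out.attrs["pair"] = pair
    out.attrs["alpha"] = alpha
    return out


def pca_scores(
    matrix: pd.DataFrame,
    standardize: bool = True,
    n_components: int | None = None,
) -> PCAResult:
    """Principal-component ordination of a subject-by-parameter table.

    Non-numeric columns (``subject``, ``group``) are ignored for the
    decomposition but retained as the score index / a ``group`` column.
    Zero-variance columns cannot be z-scored and are dropped with a
    warning.
    """
    meta_cols = [c for c in ("subject", "group") if c in matrix.columns]
    num = matrix.drop(columns=meta_cols).select_dtypes(include=[np.number])
    if num.shape[0] < 2 or num.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 numeric columns")
    dropped: list[str] = []
    X = num.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if standardize:
        keep = sd > 0
        dropped = [c for c, k in zip(num.columns, keep) if not k]
        if dropped:
            warnings.warn(
                f"dropping zero-variance columns before z-scoring: {dropped}",
                stacklevel=2,
            )
        X = (X[:, keep] - mu[keep]) / sd[keep]
        cols = [c for c, k in zip(num.columns, keep) if k]
    else:
        X = X - mu
        cols = list(num.columns)
    if X.shape[1] < 2:
        raise ValueError("fewer than 2 usable columns for PCA")
    k = n_components or min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # parameters x components

    # deterministic sign: make the dominant loading of each component positive
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    index = (
        matrix["subject"] if "subject" in matrix.columns else matrix.index
    )
    score_df = pd.DataFrame(scores, columns=comp_names, index=index)
    if "group" in matrix.columns:
        score_df.insert(0, "group", matrix["group"].to_numpy())
    loading_df = pd.DataFrame(loadings, columns=comp_names, index=cols)
    return PCAResult(
        scores=score_df,
        loadings=loading_df,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_columns=dropped,
    )
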