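"""SVD-based principal component analysis of flux datasets.

Rows are reactions (the individuals), columns are conditions (the
variables), following the convention of analysing the aggregate flux
dataset across oxygen regimes.  With ``standardize=True`` (the default)
columns are centered and scaled to unit sample variance, i.e. correlation
PCA; variable loadings are then Pearson correlations between each
condition's fluxes and the component scores and lie in [−1, 1].

Conventions, fixed so results are deterministic and comparable:

* eigenvalues are squared singular values divided by ``n_rows − 1`` (sample
  normalization; when standardized they sum to the number of conditions);
* each component's sign is chosen so that its largest-magnitude variable
  loading is positive;
* the contribution of reaction *i* to component *k* is
  ``100 · score_ik² / Σ_i score_ik²``, so contributions sum to 100% per
  component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .fba import FluxSolution

#: Fluxes with magnitude at or below this count as numerically zero.
DEFAULT_ACTIVE_TOLERANCE = 1e-9

_RANK_TOL = 1e-12


@dataclass
class FluxMatrix:
    """Flux dataset: active reactions × conditions."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    active_tolerance: float = DEFAULT_ACTIVE_TOLERANCE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class PCAResult:
    """Eigenvalues, loadings, scores and contributions of one PCA run."""

    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    variable_loadings: pd.DataFrame
    individual_scores: pd.DataFrame
    individual_contributions: pd.DataFrame
    standardized: bool
    column_means: np.ndarray = field(repr=False, default=None)
    column_sds: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass
class CorrelationMatrixResult:
    """Pairwise condition correlations with significance flags."""

    correlations: pd.DataFrame
    p_values: pd.DataFrame
    significant: pd.DataFrame
    alpha: float = 0.001


def _extract_fluxes(solution) -> pd.Series:
    if isinstance(solution, FluxSolution):
        return solution.flux_series()
    if isinstance(solution, pd.Series):
        return solution
    if isinstance(solution, Mapping):
        return pd.Series(solution, dtype=float)
    raise TypeError(f"cannot interpret {type(solution)!r} as a flux solution")


def assemble_flux_matrix(
    solutions: Mapping[str, object],
    active_tolerance: float = DEFAULT_ACTIVE_TOLERANCE,
) -> FluxMatrix:
    """Stack per-condition flux solutions and drop inactive reactions.

    A reaction is retained if its flux exceeds ``active_tolerance`` in
    magnitude in at least one condition.  All solutions must cover the same
    reaction id universe; fewer than two conditions or an empty active set
    is an error.
    """
    if len(solutions) < 2:
        raise ValueError("at least two conditions are required for PCA")
    columns = {name: _extract_fluxes(sol) for name, sol in solutions.items()}
    universes = {name: frozenset(col.index) for name, col in columns.items()}
    first = next(iter(universes.values()))
    if any(u != first for u in universes.values()):
        raise ValueError("conditions do not share a reaction id universe")
    frame = pd.DataFrame(columns)
    active = frame.abs().gt(active_tolerance).any(axis=1)
    frame = frame.loc[active]
    if frame.empty:
        raise ValueError("no reaction is active in any condition")
    return FluxMatrix(
        values=frame.to_numpy(dtype=float),
        row_ids=list(frame.index),
        col_ids=list(frame.columns),
        active_tolerance=active_tolerance,
    )


def flux_matrix_from_frame(
    frame: pd.DataFrame, active_tolerance: float = DEFAULT_ACTIVE_TOLERANCE
) -> FluxMatrix:
    """Build a :class:`FluxMatrix` from a reactions × conditions table."""
    return assemble_flux_matrix(
        {str(c): frame[c] for c in frame.columns}, active_tolerance
    )


def run_pca(matrix: FluxMatrix, standardize: bool = True) -> PCAResult:
    """Principal component analysis via singular value decomposition.

    Columns are centered (and scaled to unit variance when ``standardize``);
    the SVD of the preprocessed matrix yields scores ``UΣ``, eigenvalues
    ``Σ²/(n−1)`` and variable loadings computed as Pearson correlations
    between original columns and scores.  Components with numerically zero
    variance (beyond the matrix rank) are dropped.
    """
    X = np.asarray(matrix.values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA requires at least 2 rows and 2 columns")
    means = X.mean(axis=0)
    Xc = X - means
    sds = Xc.std(axis=0, ddof=1)
    if standardize:
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            names = [matrix.col_ids[j] for j in zero]
            raise ValueError(
                f"cannot standardize zero-variance column(s): {names}"
            )
        Xc = Xc / sds

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    rank = int(np.sum(eigenvalues > _RANK_TOL * max(eigenvalues[0], 1.0)))
    rank = max(rank, 1)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    eigenvalues = eigenvalues[:rank]
    scores = U * s

    # loadings as Pearson correlations between original columns and scores
    loadings = np.empty((p, rank))
    score_sds = scores.std(axis=0, ddof=1)
    for j in range(p):
        for k in range(rank):
            if score_sds[k] == 0 or sds[j] == 0:
                loadings[j, k] = np.nan
            else:
                loadings[j, k] = float(
                    np.cov(X[:, j], scores[:, k], ddof=1)[0, 1]
                    / (sds[j] * score_sds[k])
                )

    # sign convention: largest-magnitude loading of each component positive
    for k in range(rank):
        col = loadings[:, k]
        if np.all(np.isnan(col)):
            continue
        lead = np.nanargmax(np.abs(col))
        if col[lead] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
            Vt[k] *= -1

    ss = (scores**2).sum(axis=0)
    contributions = 100.0 * scores**2 / ss

    comp_names = [f"PC{k + 1}" for k in range(rank)]
    variance_fraction = 100.0 * eigenvalues / eigenvalues.sum()
    return PCAResult(
        eigenvalues=eigenvalues,
        variance_fraction=variance_fraction,
        variable_loadings=pd.DataFrame(
            loadings, index=matrix.col_ids, columns=comp_names
        ),
        individual_scores=pd.DataFrame(
            scores, index=matrix.row_ids, columns=comp_names
        ),
        individual_contributions=pd.DataFrame(
            contributions, index=matrix.row_ids, columns=comp_names
        ),
        standardized=standardize,
        column_means=means,
        column_sds=sds,
    )


def variable_correlations(result: PCAResult) -> pd.DataFrame:
    """Condition × component table of variable loadings.

    Entries are the Pearson correlations between each original condition
    column and the component scores (identical to the stored loadings).
    """
    return result.variable_loadings.copy()


def individual_contributions(
    result: PCAResult, top_n: int | None = None
) -> pd.DataFrame:
    """Per-reaction percent contributions, ranked by PC1 contribution.

    Ties are broken by reaction id so the ranking is deterministic.
    """
    # mergesort is stable, so pre-sorting by id makes id the tiebreak
    table = (
        result.individual_contributions.loc[
            sorted(result.individual_contributions.index)
        ]
        .sort_values(by="PC1", ascending=False, kind="mergesort")
    )
    if top_n is not None:
        table = table.head(top_n)
    return table


def condition_correlation_matrix(matrix: FluxMatrix) -> CorrelationMatrixResult:
    """Pearson correlations between condition columns with p < 0.001 flags.

    Two-sided p-values come from the t-distribution on ``n_rows − 2``
    degrees of freedom; a constant column yields undefined correlations,
    reported as missing with a warning.
    """
    if matrix.n_rows < 3:
        raise ValueError("correlation significance requires at least 3 rows")
    p = matrix.n_cols
    X = matrix.values
    corr = np.ones((p, p))
    pvals = np.zeros((p, p))
    constant = [j for j in range(p) if np.ptp(X[:, j]) == 0]
    if constant:
        warnings.warn(
            "constant condition column(s) "
            f"{[matrix.col_ids[j] for j in constant]}: correlation undefined"
        )
    for i in range(p):
        for j in range(i + 1, p):
            if i in constant or j in constant:
                r, pv = np.nan, np.nan
            else:
                r, pv = stats.pearsonr(X[:, i], X[:, j])
            corr[i, j] = corr[j, i] = r
            pvals[i, j] = pvals[j, i] = pv
    ids = matrix.col_ids
    corr_df = pd.DataFrame(corr, index=ids, columns=ids)
    p_df = pd.DataFrame(pvals, index=ids, columns=ids)
    return CorrelationMatrixResult(
        correlations=corr_df,
        p_values=p_df,
        significant=(p_df < 0.001) & np.isfinite(p_df),
    )
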