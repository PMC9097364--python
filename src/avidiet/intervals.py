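"""FE post-processing: MWAM strain, strain-interval profiles treated as
compositions, zero imputation, log-ratio transforms, and interval-count
convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr

from .errors import CompositionError

__all__ = [
    "StrainField",
    "StrainProfile",
    "TransformedProfileMatrix",
    "mwam",
    "interval_profile",
    "profile_matrix",
    "impute_zeros",
    "clr",
    "ilr",
    "converge_intervals",
    "ConvergenceReport",
]


@dataclass(frozen=True)
class StrainField:
    """Per-element strain magnitudes (microstrain) and areas for one model."""

    strain: np.ndarray
    area: np.ndarray
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "strain", np.asarray(self.strain, dtype=float))
        object.__setattr__(self, "area", np.asarray(self.area, dtype=float))
        if self.strain.shape != self.area.shape:
            raise ValueError("strain and area must have the same shape")
        if self.strain.size == 0:
            raise ValueError("empty strain field")
        if np.any(self.area <= 0):
            raise ValueError("element areas must be positive")
        if np.any(self.strain < 0):
            raise ValueError("strain magnitudes must be non-negative")


@dataclass(frozen=True)
class StrainProfile:
    """Percent model area per equal-width strain interval."""

    label: str
    n_intervals: int
    lo: float
    hi: float
    percent_area: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "percent_area",
                           np.asarray(self.percent_area, dtype=float))
        if len(self.percent_area) != self.n_intervals:
            raise ValueError("percent_area length must equal n_intervals")
        if np.any(self.percent_area < 0):
            raise ValueError("percent areas must be non-negative")
        if abs(self.percent_area.sum() - 100.0) > 1e-9:
            raise ValueError(f"percent areas sum to {self.percent_area.sum()}, want 100")


def mwam(f: StrainField) -> float:
    """Mesh-weighted arithmetic mean strain: sum(strain*area)/sum(area)."""
    return float(np.sum(f.strain * f.area) / np.sum(f.area))


def interval_profile(f: StrainField, n: int, strain_range: tuple[float, float]) -> StrainProfile:
    """Percent area per interval over a shared [lo, hi) grid, last bin closed."""
    lo, hi = strain_range
    if n < 2:
        raise ValueError("need at least 2 intervals")
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if np.any(f.strain < lo) or np.any(f.strain > hi):
        raise ValueError(
            "strain outside the stated range: compute a global range over all "
            "models in the comparison first")
    edges = np.linspace(lo, hi, n + 1)
    idx = np.minimum(np.searchsorted(edges, f.strain, side="right") - 1, n - 1)
    idx = np.maximum(idx, 0)
    area = np.bincount(idx, weights=f.area, minlength=n)
    pct = 100.0 * area / area.sum()
    pct = pct * (100.0 / pct.sum())  # exact closure
    return StrainProfile(label=f.label, n_intervals=n, lo=lo, hi=hi, percent_area=pct)


def profile_matrix(fields: list[StrainField], n: int,
                   strain_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Stack profiles for a comparison set; range defaults to [0, global max]."""
    if strain_range is None:
        strain_range = (0.0, max(float(f.strain.max()) for f in fields))
    rows = [interval_profile(f, n, strain_range).percent_area for f in fields]
    cols = [f"int_{k}" for k in range(n)]
    return pd.DataFrame(rows, index=[f.label for f in fields], columns=cols)


# ---------------------------------------------------------------------------
# Compositional machinery


def _truncated_lognormal_mean(mu: float, sigma: float, limit: float) -> float:
    """E[X | X < limit] for X ~ lognormal(mu, sigma)."""
    if sigma <= 0:
        return 0.65 * limit
    z = (np.log(limit) - mu) / sigma
    denom = norm.cdf(z)
    if denom <= 0:
        return 0.65 * limit
    val = np.exp(mu + 0.5 * sigma ** 2) * norm.cdf(z - sigma) / denom
    # guard against numerical overshoot at tiny sigma
    return float(min(val, 0.999999 * limit))


def impute_zeros(M: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Replace zeros with sub-detection-limit lognormal expected values.

    Each zero in a column is replaced by the expected value of a lognormal
    fitted (moments of log nonzero entries) truncated at the column detection
    limit (smallest observed nonzero); nonzero entries of affected rows are
    multiplicatively rescaled so every row still sums to 100.  All-zero
    columns are dropped with a warning.  Returns the positive matrix and an
    imputation record.
    """
    X = M.to_numpy(dtype=float).copy()
    if np.any(X < 0) or np.any(X > 100):
        raise CompositionError("profile entries must lie in [0, 100]")
    if np.any(np.abs(X.sum(axis=1) - 100.0) > 1e-6):
        raise CompositionError("every profile row must sum to 100")
    record: dict = {"replaced": [], "dropped_columns": []}

    all_zero = np.all(X == 0, axis=0)
    if all_zero.any():
        dropped = [str(c) for c, z in zip(M.columns, all_zero) if z]
        warnings.warn(f"dropping all-zero columns: {dropped}", stacklevel=2)
        record["dropped_columns"] = dropped
        keep = ~all_zero
        X = X[:, keep]
        columns = [c for c, k in zip(M.columns, keep) if k]
    else:
        columns = list(M.columns)

    if not np.any(X == 0):
        return pd.DataFrame(X, index=M.index, columns=columns), record

    imputed = np.zeros_like(X, dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        zeros = col == 0
        if not zeros.any():
            continue
        nz = col[~zeros]
        limit = float(nz.min())
        logs = np.log(nz)
        mu = float(logs.mean())
        sigma = float(logs.std(ddof=1)) if len(np.unique(nz)) > 1 else 0.0
        value = _truncated_lognormal_mean(mu, sigma, limit)
        X[zeros, j] = value
        imputed[zeros, j] = True
        for i in np.where(zeros)[0]:
            record["replaced"].append(
                {"row": str(M.index[i]), "column": str(columns[j]), "value": value})

    # multiplicative row closure: imputed cells stay, others rescale
    for i in range(X.shape[0]):
        imp_sum = X[i, imputed[i]].sum()
        rest = X[i, ~imputed[i]].sum()
        if rest <= 0:
            raise CompositionError(f"row {M.index[i]} has no observed mass left")
        X[i, ~imputed[i]] *= (100.0 - imp_sum) / rest
    return pd.DataFrame(X, index=M.index, columns=columns), record


def clr(row) -> np.ndarray:
    """Centred log-ratio: ln(x_i / geometric mean); output sums to 0."""
    x = np.asarray(row, dtype=float)
    if np.any(x <= 0):
        raise CompositionError("clr requires strictly positive components")
    logx = np.log(x)
    return logx - logx.mean()


def ilr(row) -> np.ndarray:
    """Isometric log-ratio, pivot basis: sqrt(i/(i+1)) ln(gm(x_1..x_i)/x_{i+1})."""
    x = np.asarray(row, dtype=float)
    if np.any(x <= 0):
        raise CompositionError("ilr requires strictly positive components")
    logx = np.log(x)
    D = len(x)
    out = np.empty(D - 1)
    csum = np.cumsum(logx)
    for i in range(1, D):
        gm_log = csum[i - 1] / i
        out[i - 1] = np.sqrt(i / (i + 1.0)) * (gm_log - logx[i])
    return out


@dataclass(frozen=True)
class TransformedProfileMatrix:
    """Model x coordinate matrix after clr or ilr, with provenance."""

    values: pd.DataFrame
    transform: str
    imputation_record: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.transform not in ("clr", "ilr"):
            raise ValueError("transform must be 'clr' or 'ilr'")
        if self.transform == "clr":
            sums = self.values.to_numpy().sum(axis=1)
            if np.any(np.abs(sums) > 1e-9):
                raise ValueError("clr rows must sum to 0")


def transform_profiles(M: pd.DataFrame, transform: str = "ilr") -> TransformedProfileMatrix:
    """Impute zeros then apply the requested log-ratio transform row-wise."""
    imputed, record = impute_zeros(M)
    fn = {"clr": clr, "ilr": ilr}[transform]
    rows = np.vstack([fn(r) for r in imputed.to_numpy()])
    if transform == "clr":
        cols = list(imputed.columns)
    else:
        cols = [f"ilr_{k}" for k in range(rows.shape[1])]
    return TransformedProfileMatrix(
        values=pd.DataFrame(rows, index=imputed.index, columns=cols),
        transform=transform,
        imputation_record=record,
    )


# ---------------------------------------------------------------------------
# Interval-count convergence


@dataclass(frozen=True)
class ConvergenceReport:
    chosen_n: int
    candidates: tuple[int, ...]
    correlations: tuple[float, ...]  # between consecutive candidate counts
    converged: bool


def converge_intervals(fields: list[StrainField], candidates, tol: float = 0.01,
                       strain_range: tuple[float, float] | None = None) -> ConvergenceReport:
    """Choose the smallest interval count whose inter-model distance structure
    is stable (correlation with the next count >= 1 - tol)."""
    cands = sorted(int(c) for c in candidates)
    if len(cands) < 2:
        raise ValueError("need at least 2 candidate interval counts")
    if strain_range is None:
        strain_range = (0.0, max(float(f.strain.max()) for f in fields))

    def dist_vec(n: int) -> np.ndarray:
        M = profile_matrix(fields, n, strain_range)
        T = transform_profiles(M, "ilr").values.to_numpy()
        diff = T[:, None, :] - T[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
        iu = np.triu_indices(len(fields), k=1)
        return D[iu]

    vecs = [dist_vec(n) for n in cands]
    corrs = []
    for a, b in zip(vecs[:-1], vecs[1:]):
        if np.allclose(a, a[0]) and np.allclose(b, b[0]):
            corrs.append(1.0)
        else:
            corrs.append(float(pearsonr(a, b)[0]))
    if any(c2 < c1 - 1e-9 for c1, c2 in zip(corrs[:-1], corrs[1:])):
        warnings.warn("convergence diagnostic is not monotone non-decreasing",
                      stacklevel=2)
    for n, c in zip(cands[:-1], corrs):
        if c >= 1.0 - tol:
            return ConvergenceReport(chosen_n=n, candidates=tuple(cands),
                                     correlations=tuple(corrs), converged=True)
    warnings.warn("no interval count converged; returning the largest candidate",
                  stacklevel=2)
    return ConvergenceReport(chosen_n=cands[-1], candidates=tuple(cands),
                             correlations=tuple(corrs), converged=False)
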