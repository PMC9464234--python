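"""Constrained ordination (RDA) and EOF analysis.

RDA regresses a multivariate response on constraint variables and
eigen-decomposes the fitted values; partial RDA residualizes both sides
on a conditioning matrix first.  Significance uses seeded row
permutations of the constraints with the add-one rule.  Variance
partitioning between two constraints reports total, unique and shared
fractions of the response inertia.

EOF analysis is principal component analysis of a time x units anomaly
field; spatial structure is reported as the Pearson correlation between
each unit's series and the leading principal component, with signs fixed
so the spatial-mean loading is non-negative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .types import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RdaResult:
    eig_constrained: np.ndarray
    eig_unconstrained: np.ndarray
    lambda_ratio: float                 # first constrained / first unconstrained
    var_explained: float                # fraction of total response inertia
    p_value: float | None = None
    total_inertia: float = np.nan


@dataclass
class VariancePartition:
    total_x1: float
    total_x2: float
    unique_x1: float
    unique_x2: float
    shared: float
    combined: float
    p_x1: float | None = None
    p_x2: float | None = None


def _as_2d(a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _project(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Least-squares projection of Y onto the column space of X."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return X @ beta


class RDA(BaseEstimator):
    """Redundancy analysis as a scikit-learn style estimator.

    Parameters
    ----------
    scale : bool
        Standardize response columns to unit variance after centering
        (PFT scores are on heterogeneous scales).
    n_permutations : int
        Constraint-row permutations for the significance test; 0 skips it.
    random_state : int or None
        Seed for the permutation test.

    Fitted attributes (trailing underscore): ``eig_constrained_``,
    ``eig_unconstrained_``, ``lambda_ratio_``, ``var_explained_``,
    ``p_value_``, ``total_inertia_``.
    """

    def __init__(self, scale: bool = True, n_permutations: int = 0,
                 random_state: int | None = None):
        self.scale = scale
        self.n_permutations = n_permutations
        self.random_state = random_state

    def _prepare_response(self, Y: np.ndarray) -> np.ndarray:
        Yc = Y - Y.mean(axis=0)
        if self.scale:
            sd = Yc.std(axis=0, ddof=1)
            keep = sd > 0
            if not np.all(keep):
                logger.warning("dropping %d zero-variance response columns", (~keep).sum())
            Yc = Yc[:, keep] / sd[keep]
        return Yc

    @staticmethod
    def _fit_core(Yc: np.ndarray, Xc: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        n = Yc.shape[0]
        fitted = _project(Xc, Yc)
        resid = Yc - fitted
        sf = np.linalg.svd(fitted, compute_uv=False)
        sr = np.linalg.svd(resid, compute_uv=False)
        eig_c = sf**2 / (n - 1)
        eig_u = sr**2 / (n - 1)
        tol = max(eig_c.max(initial=0.0), eig_u.max(initial=0.0)) * 1e-10
        return eig_c[eig_c > tol], eig_u[eig_u > tol], float(np.sum(fitted**2) / (n - 1))

    def fit(self, X, Y, Z=None):
        """Fit the ordination of response ``Y`` constrained by ``X``.

        ``Z`` is an optional conditioning matrix (partial RDA): both the
        response and the constraints are residualized on it first, but
        inertia fractions stay relative to the unconditioned response.
        """
        X = _as_2d(X)
        Yc = self._prepare_response(_as_2d(Y))
        n = Yc.shape[0]
        if X.shape[0] != n:
            raise ValidationError("X and Y sample counts differ")
        total = float(np.sum(Yc**2) / (n - 1))
        Xc = X - X.mean(axis=0)
        if Z is not None:
            Zc = _as_2d(Z)
            Zc = Zc - Zc.mean(axis=0)
            Yc = Yc - _project(Zc, Yc)
            Xc = Xc - _project(Zc, Xc)
        if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
            raise ValidationError("constraint matrix rank-deficient (after conditioning)")
        eig_c, eig_u, cons = self._fit_core(Yc, Xc)
        self.eig_constrained_ = eig_c
        self.eig_unconstrained_ = eig_u
        self.total_inertia_ = total
        self.var_explained_ = cons / total if total > 0 else 0.0
        self.lambda_ratio_ = (float(eig_c[0] / eig_u[0])
                              if eig_c.size and eig_u.size else np.inf)
        self.p_value_ = None
        if self.n_permutations:
            rng = np.random.default_rng(self.random_state)
            obs = self.var_explained_
            count = 0
            for _ in range(self.n_permutations):
                perm = rng.permutation(n)
                _, _, cons_p = self._fit_core(Yc, Xc[perm])
                if cons_p / total >= obs - 1e-12:
                    count += 1
            self.p_value_ = (1 + count) / (1 + self.n_permutations)
        return self

    def result(self) -> RdaResult:
        return RdaResult(
            eig_constrained=self.eig_constrained_,
            eig_unconstrained=self.eig_unconstrained_,
            lambda_ratio=self.lambda_ratio_,
            var_explained=self.var_explained_,
            p_value=self.p_value_,
            total_inertia=self.total_inertia_,
        )


def rda(Y, X, Z=None, n_perm: int = 0, seed: int | None = None,
        scale: bool = True) -> RdaResult:
    """Functional wrapper over :class:`RDA`."""
    est = RDA(scale=scale, n_permutations=n_perm, random_state=seed)
    est.fit(X, Y, Z=Z)
    return est.result()


def _explained_fraction(Y, X, Z=None, scale: bool = True) -> float:
    """Constrained-inertia fraction via a rank-tolerant projection.

    Unlike :func:`rda` this does not reject rank-deficient constraints:
    aliased columns simply add nothing, which is the convention needed
    for variance partitioning (a duplicated constraint has zero unique
    share rather than being an error).
    """
    est = RDA(scale=scale)
    Yc = est._prepare_response(_as_2d(np.asarray(Y, dtype=float)))
    n = Yc.shape[0]
    total = float(np.sum(Yc**2))
    Xc = _as_2d(X) - _as_2d(X).mean(axis=0)
    if Z is not None:
        Zc = _as_2d(Z) - _as_2d(Z).mean(axis=0)
        Yc = Yc - _project(Zc, Yc)
        Xc = Xc - _project(Zc, Xc)
    norm = np.linalg.norm(Xc)
    if norm < 1e-12 or total == 0.0:
        return 0.0
    fitted = _project(Xc, Yc)
    return float(np.sum(fitted**2) / total)


def variance_partition(Y, x1, x2, n_perm: int = 0, seed: int | None = None,
                       scale: bool = True) -> VariancePartition:
    """Partition response inertia between two constraint variables.

    ``total_xi`` comes from simple RDA on xi alone, ``unique_xi`` from
    partial RDA of xi conditioned on the other, ``combined`` from both
    jointly; ``shared = combined - unique_x1 - unique_x2`` and may be
    negative in suppressor configurations.  Collinear constraints are
    tolerated (a duplicated variable has zero unique share).
    """
    x1 = _as_2d(x1)
    x2 = _as_2d(x2)
    r1 = rda(Y, x1, n_perm=n_perm, seed=seed, scale=scale)
    r2 = rda(Y, x2, n_perm=n_perm, seed=None if seed is None else seed + 1, scale=scale)
    combined = _explained_fraction(Y, np.hstack([x1, x2]), scale=scale)
    u1 = _explained_fraction(Y, x1, Z=x2, scale=scale)
    u2 = _explained_fraction(Y, x2, Z=x1, scale=scale)
    shared = combined - u1 - u2
    return VariancePartition(
        total_x1=r1.var_explained, total_x2=r2.var_explained,
        unique_x1=u1, unique_x2=u2,
        shared=shared, combined=combined,
        p_x1=r1.p_value, p_x2=r2.p_value,
    )


# ------------------------------------------------------------------- EOF

@dataclass
class EofResult:
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    pcs: np.ndarray                     # time x modes scores
    loadings: np.ndarray                # units x modes
    correlation_map: np.ndarray         # per unit, Pearson r with PC1
    unit_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


class EOF(BaseEstimator):
    """Empirical orthogonal functions of a time x units anomaly field.

    Units with more than ``max_missing`` missing fraction in the analysis
    window are dropped; remaining gaps are linearly interpolated in time.
    Modes come from the covariance matrix of the unit series; variance
    fractions sum to 1 over all retained modes.
    """

    def __init__(self, max_missing: float = 0.2):
        self.max_missing = max_missing

    def fit(self, field: np.ndarray, times: np.ndarray | None = None):
        F = np.asarray(field, dtype=float)
        if F.ndim != 2 or F.shape[1] < 2:
            raise ValidationError("EOF needs a time x units matrix with >=2 units")
        nt, nu = F.shape
        t = np.arange(nt, dtype=float) if times is None else np.asarray(times, float)
        miss_frac = np.isnan(F).mean(axis=0)
        keep = miss_frac <= self.max_missing
        dropped = np.nonzero(~keep)[0]
        if dropped.size:
            logger.warning("EOF: dropping %d units with >%.0f%% missing bins",
                           dropped.size, 100 * self.max_missing)
        F = F[:, keep]
        for j in range(F.shape[1]):
            col = F[:, j]
            if np.any(np.isnan(col)):
                ok = ~np.isnan(col)
                F[:, j] = np.interp(t, t[ok], col[ok])
        var = F.var(axis=0, ddof=1)
        zero = var <= 0
        if np.any(zero):
            warnings.warn(f"EOF: excluding {int(zero.sum())} zero-variance units")
            idx_keep = np.nonzero(keep)[0][~zero]
            F = F[:, ~zero]
        else:
            idx_keep = np.nonzero(keep)[0]
        if F.shape[1] < 2:
            raise ValidationError("EOF needs >=2 usable units")
        Fc = F - F.mean(axis=0)
        U, s, Vt = np.linalg.svd(Fc, full_matrices=False)
        eig = s**2 / (Fc.shape[0] - 1)
        loadings = Vt.T                                 # units x modes
        pcs = U * s                                     # time x modes
        # sign convention: spatial-mean loading non-negative per mode
        signs = np.where(loadings.mean(axis=0) < 0, -1.0, 1.0)
        loadings = loadings * signs
        pcs = pcs * signs
        pc1 = pcs[:, 0]
        with np.errstate(invalid="ignore"):
            cmap = np.array([np.corrcoef(F[:, j], pc1)[0, 1] for j in range(F.shape[1])])
        self.eigenvalues_ = eig
        self.variance_fractions_ = eig / eig.sum()
        self.pcs_ = pcs
        self.loadings_ = loadings
        self.correlation_map_ = cmap
        self.unit_index_ = idx_keep
        return self

    def result(self) -> EofResult:
        return EofResult(
            eigenvalues=self.eigenvalues_,
            variance_fractions=self.variance_fractions_,
            pcs=self.pcs_,
            loadings=self.loadings_,
            correlation_map=self.correlation_map_,
            unit_index=self.unit_index_,
        )


def eof(field: np.ndarray, times: np.ndarray | None = None,
        window: tuple[float, float] | None = None,
        max_missing: float = 0.2) -> EofResult:
    """EOF of an anomaly field, optionally restricted to an age window.

    ``window`` is a (young, old) interval in the same units as ``times``
    (e.g. cal yr BP); rows with times inside [young, old] are analysed.
    """
    F = np.asarray(field, dtype=float)
    if window is not None:
        if times is None:
            raise ValidationError("window requires a time axis")
        times = np.asarray(times, float)
        lo, hi = min(window), max(window)
        sel = (times >= lo) & (times <= hi)
        F = F[sel]
        times = times[sel]
    est = EOF(max_missing=max_missing)
    est.fit(F, times=times)
    return est.result()
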