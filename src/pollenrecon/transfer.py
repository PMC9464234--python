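"""Transfer functions: MAT, WA-PLS, cross-validation and significance.

The modern analogue technique (MAT) assigns each fossil assemblage the
dissimilarity-weighted climate of its k closest modern surface samples,
closeness measured by the squared chord distance (SCD).  Samples whose
nearest analogue exceeds an SCD threshold are flagged as no-analogue.
Sample-specific errors combine a bootstrap spread of the calibration set
with the cross-validated RMSEP in quadrature.  Spatial autocorrelation
is handled by h-block cross-validation (the test sample plus all sites
within h km are withheld), with h chosen by matching the median fossil
SCD to the median nearest-analogue SCD of the changing-h experiments.
Reconstruction significance follows the random-transfer-function test:
a reconstruction must explain more fossil-assemblage variance (as a sole
RDA constraint) than a stated share of reconstructions trained on random
environmental variables.

WA-PLS (weighted-averaging partial least squares) is provided as a
cross-check method, in the iterative species-weighted formulation with
inverse deshrinking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin

from .types import CalibrationSet, ValidationError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
DEFAULT_K = 6
DEFAULT_SCD_MAX = 0.2


# ------------------------------------------------------------ distances

def scd(p: np.ndarray, q: np.ndarray, normalize: bool = False) -> float:
    """Squared chord distance sum((sqrt(p)-sqrt(q))^2) between two vectors."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("scd vectors must have equal length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValidationError("scd requires non-negative entries")
    if normalize:
        p = p / p.sum()
        q = q / q.sum()
    return float(np.sum((np.sqrt(p) - np.sqrt(q)) ** 2))


def _row_normalize(A: np.ndarray) -> np.ndarray:
    sums = A.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError("cannot normalize rows with non-positive sums")
    return A / sums


def pairwise_scd(A: np.ndarray, B: np.ndarray, normalize: bool = True) -> np.ndarray:
    """SCD between every row of A and every row of B."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(A < 0) or np.any(B < 0):
        raise ValidationError("scd requires non-negative entries")
    if normalize:
        A = _row_normalize(A)
        B = _row_normalize(B)
    return cdist(np.sqrt(A), np.sqrt(B), metric="sqeuclidean")


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a 6371-km sphere."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    a = (np.sin((la2 - la1) / 2) ** 2
         + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def site_distance_matrix(coords: np.ndarray) -> np.ndarray:
    lat = coords[:, 0][:, None]
    lon = coords[:, 1][:, None]
    return haversine_km(lat, lon, lat.T, lon.T)


# ------------------------------------------------------------------ MAT

class MATRegressor(BaseEstimator, RegressorMixin):
    """Modern analogue technique as a k-nearest-analogue regressor.

    Parameters
    ----------
    k : int
        Number of analogues (5-7 is conventional; default 6).
    scd_max : float
        No-analogue threshold on the nearest-analogue SCD; predictions
        above it are withheld (NaN) in detailed output.
    normalize : bool
        Row-normalize assemblages to sum 1 before the chord transform.
    """

    def __init__(self, k: int = DEFAULT_K, scd_max: float = DEFAULT_SCD_MAX,
                 normalize: bool = True):
        self.k = k
        self.scd_max = scd_max
        self.normalize = normalize

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if X.shape[0] == 0:
            raise ValidationError("empty calibration set")
        self.X_ = X
        self.y_ = y[:, None] if y.ndim == 1 else y
        self._squeeze = y.ndim == 1
        return self

    def predict_detailed(self, X, exclude: np.ndarray | None = None) -> dict:
        """Predict with diagnostics.

        ``exclude`` is an optional boolean mask, shape (n_targets,
        n_calibration), True where a calibration sample may not be used
        for that target (h-block / leave-one-out pools).
        """
        X = np.asarray(X, dtype=float)
        d = pairwise_scd(X, self.X_, normalize=self.normalize)
        if exclude is not None:
            d = d.copy()
            d[exclude] = np.inf
            if np.any(np.all(~np.isfinite(d), axis=1)):
                raise ValidationError("all calibration candidates excluded for a target")
        m, n = d.shape
        k = min(self.k, n)
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        rows = np.arange(m)[:, None]
        dk = d[rows, order]
        est = np.empty((m, self.y_.shape[1]))
        for i in range(m):
            di = dk[i]
            fin = np.isfinite(di)
            di, idx = di[fin], order[i][fin]
            if di.size == 0:
                raise ValidationError("all calibration candidates excluded for a target")
            if di[0] == 0.0:
                zero = di == 0.0
                est[i] = self.y_[idx[zero]].mean(axis=0)
            else:
                w = 1.0 / di
                est[i] = (w[:, None] * self.y_[idx]).sum(axis=0) / w.sum()
        min_scd = dk[:, 0]
        no_analogue = min_scd > self.scd_max
        est_out = est.copy()
        est_out[no_analogue] = np.nan
        return {
            "estimate": est_out,
            "estimate_all": est,
            "min_scd": min_scd,
            "analogue_idx": order,
            "analogue_scd": dk,
            "no_analogue": no_analogue,
        }

    def predict(self, X):
        est = self.predict_detailed(X)["estimate_all"]
        return est[:, 0] if self._squeeze else est


def mat_predict(target: np.ndarray, calib: CalibrationSet, k: int = DEFAULT_K,
                scd_max: float = DEFAULT_SCD_MAX,
                exclude=None) -> tuple[np.ndarray, dict]:
    """Functional MAT: estimates for all three climate variables.

    ``exclude`` may be a site predicate ``f(Site) -> bool`` (True =
    excluded) or a boolean mask over calibration samples.
    """
    model = MATRegressor(k=k, scd_max=scd_max).fit(
        calib.features, calib.climate.to_numpy())
    target = np.atleast_2d(np.asarray(target, dtype=float))
    mask = None
    if exclude is not None:
        if callable(exclude):
            excl = np.array([bool(exclude(s)) for s in calib.sites])
        else:
            excl = np.asarray(exclude, dtype=bool)
        if excl.all():
            raise ValidationError("all calibration candidates excluded")
        mask = np.broadcast_to(excl, (target.shape[0], excl.size))
    out = model.predict_detailed(target, exclude=mask)
    return out["estimate"], out


def bootstrap_error(target: np.ndarray, calib: CalibrationSet, k: int = DEFAULT_K,
                    n_boot: int = 100, rmsep: float | np.ndarray = 0.0,
                    seed: int | None = None) -> np.ndarray:
    """Sample-specific error: bootstrap SD of MAT predictions + RMSEP.

    The calibration rows are resampled with replacement ``n_boot`` times;
    each resample yields a MAT prediction for every target row, and the
    per-target SD across resamples is combined with the model RMSEP in
    quadrature.  Returns shape (n_targets, n_variables).
    """
    rng = np.random.default_rng(seed)
    target = np.atleast_2d(np.asarray(target, dtype=float))
    y = calib.climate.to_numpy()
    d_all = pairwise_scd(target, calib.features, normalize=True)
    n = y.shape[0]
    m = target.shape[0]
    k = min(k, n)
    rmsep = np.broadcast_to(np.asarray(rmsep, dtype=float), (y.shape[1],))
    preds = np.empty((n_boot, m, y.shape[1]))
    eps = 1e-12
    for b in range(n_boot):
        for _ in range(10):                      # redraw guard for degenerate resamples
            idx = rng.integers(0, n, size=n)
            db = d_all[:, idx]
            if np.all(np.isfinite(db).any(axis=1)):
                break
        order = np.argpartition(db, k - 1, axis=1)[:, :k]
        rows = np.arange(m)[:, None]
        dk = np.maximum(db[rows, order], eps)    # ~short-circuits zero distances
        w = 1.0 / dk
        yb = y[idx][order]                       # m x k x v
        preds[b] = (w[:, :, None] * yb).sum(axis=1) / w.sum(axis=1)[:, None]
    sd = preds.std(axis=0, ddof=1)
    return np.sqrt(sd**2 + rmsep[None, :] ** 2)


# --------------------------------------------------------------- WA-PLS

class WAPLSRegressor(BaseEstimator, RegressorMixin):
    """Weighted-averaging partial least squares transfer function.

    Iterative formulation: per component, species scores are the
    species-weighted average of the current environmental residual, site
    scores the sample-weighted average of species scores, orthogonalized
    against earlier components and standardized under site-total weights;
    the running residual comes from a weighted regression of the (site-
    weight-centred) variable on the components so far.  That final
    regression is the inverse deshrinking; a classical variant regresses
    the composite score on the observed variable and inverts.
    """

    def __init__(self, n_components: int = 2, deshrinking: str = "inverse"):
        self.n_components = n_components
        self.deshrinking = deshrinking

    def fit(self, X, y):
        Y = np.asarray(X, dtype=float)
        x = np.asarray(y, dtype=float).ravel()
        if np.any(Y < 0):
            raise ValidationError("WA-PLS features must be non-negative")
        if self.n_components < 1:
            raise ValidationError("n_components must be >= 1")
        if self.deshrinking not in ("inverse", "classical"):
            raise ValidationError("deshrinking must be 'inverse' or 'classical'")
        n, _ = Y.shape
        col_ok = Y.sum(axis=0) > 0
        Y = Y[:, col_ok]
        self._col_ok = col_ok
        R = Y.sum(axis=1)
        if np.any(R <= 0):
            raise ValidationError("WA-PLS samples must have positive totals")
        C = Y.sum(axis=0)
        w = R / R.sum()
        if self.n_components > min(n - 1, Y.shape[1]):
            raise ValidationError(
                f"n_components={self.n_components} exceeds feasible rank "
                f"{min(n - 1, Y.shape[1])}")
        xbar = float(np.sum(w * x))
        x0 = x - xbar
        r = x0.copy()
        ncomp = self.n_components
        U = np.zeros((Y.shape[1], ncomp))
        Z = np.zeros((n, ncomp))
        orth: list[list[float]] = []
        means, sds, betas = [], [], []
        for a in range(ncomp):
            u = (Y.T @ r) / C
            z = (Y @ u) / R
            coefs = []
            for b in range(a):
                c = float(np.sum(w * z * Z[:, b]))
                z = z - c * Z[:, b]
                coefs.append(c)
            mz = float(np.sum(w * z))
            z = z - mz
            sz = float(np.sqrt(np.sum(w * z**2)))
            if sz < 1e-12:
                raise ValidationError(
                    f"component {a + 1} is degenerate; reduce n_components")
            z = z / sz
            U[:, a] = u
            Z[:, a] = z
            orth.append(coefs)
            means.append(mz)
            sds.append(sz)
            A = Z[:, : a + 1]
            Aw = A * w[:, None]
            beta = np.linalg.solve(Aw.T @ A, Aw.T @ x0)
            betas.append(beta)
            r = x0 - A @ beta
        self.species_scores_ = U
        self.site_scores_ = Z
        self._orth = orth
        self._means = means
        self._sds = sds
        self.betas_ = betas
        self.x_mean_ = xbar
        self._w = w
        fitted = xbar + Z @ betas[-1]
        if self.deshrinking == "classical":
            # regress the composite score on the observed variable, invert
            sw = np.sum(w)
            xb = np.sum(w * x) / sw
            fb = np.sum(w * fitted) / sw
            b1 = np.sum(w * (x - xb) * (fitted - fb)) / np.sum(w * (x - xb) ** 2)
            b0 = fb - b1 * xb
            self._deshrink = (b0, b1)
            fitted = (fitted - b0) / b1
        else:
            self._deshrink = None
        self.fitted_values_ = fitted
        self.x_ = x
        return self

    def _scores_new(self, Yn: np.ndarray, ncomp: int) -> np.ndarray:
        Rn = Yn.sum(axis=1)
        if np.any(Rn <= 0):
            raise ValidationError("prediction samples must have positive totals")
        Zn = np.zeros((Yn.shape[0], ncomp))
        for a in range(ncomp):
            z = (Yn @ self.species_scores_[:, a]) / Rn
            for b, c in enumerate(self._orth[a]):
                z = z - c * Zn[:, b]
            z = (z - self._means[a]) / self._sds[a]
            Zn[:, a] = z
        return Zn

    def predict(self, X, n_components: int | None = None):
        Yn = np.asarray(X, dtype=float)[:, self._col_ok]
        ncomp = self.n_components if n_components is None else n_components
        if not 1 <= ncomp <= self.n_components:
            raise ValidationError("n_components out of fitted range")
        Zn = self._scores_new(Yn, ncomp)
        pred = self.x_mean_ + Zn @ self.betas_[ncomp - 1]
        if self._deshrink is not None:
            b0, b1 = self._deshrink
            pred = (pred - b0) / b1
        return pred

    def training_r2(self, n_components: int | None = None) -> float:
        """Weighted training R^2 for a nested component count."""
        ncomp = self.n_components if n_components is None else n_components
        fitted = self.x_mean_ + self.site_scores_[:, :ncomp] @ self.betas_[ncomp - 1]
        w = self._w
        resid = self.x_ - fitted
        tot = np.sum(w * (self.x_ - np.sum(w * self.x_)) ** 2)
        return float(1.0 - np.sum(w * resid**2) / tot)


def wapls_fit(calib: CalibrationSet, n_comp: int, variable: str = "mtco",
              deshrinking: str = "inverse") -> WAPLSRegressor:
    model = WAPLSRegressor(n_components=n_comp, deshrinking=deshrinking)
    return model.fit(calib.features, calib.climate[variable].to_numpy())


def wapls_predict(model: WAPLSRegressor, target: np.ndarray) -> np.ndarray:
    return model.predict(np.atleast_2d(np.asarray(target, dtype=float)))


def wapls_select_ncomp(X, y, max_comp: int = 5, n_folds: int = 5,
                       seed: int | None = None) -> int:
    """Component count minimizing k-fold cross-validated RMSEP."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    folds = rng.permutation(n) % n_folds
    max_comp = min(max_comp, min(n - int(np.ceil(n / n_folds)) - 1, X.shape[1]))
    sse = np.zeros(max_comp)
    for f in range(n_folds):
        test = folds == f
        model = WAPLSRegressor(n_components=max_comp).fit(X[~test], y[~test])
        for a in range(1, max_comp + 1):
            pred = model.predict(X[test], n_components=a)
            sse[a - 1] += np.sum((pred - y[test]) ** 2)
    return int(np.argmin(sse)) + 1


# ----------------------------------------------------- cross-validation

@dataclass
class CvResult:
    method: str                     # MAT | WAPLS
    scheme: str                     # loo | h_block
    h: float                        # km (0 for loo)
    r2: dict                        # variable -> squared Pearson r
    rmsep: dict                     # variable -> deg C
    predictions: pd.DataFrame
    n_dropped: int = 0


def cross_validate(calib: CalibrationSet, method: str = "mat",
                   scheme: str = "loo", h: float = 0.0,
                   seed: int | None = None, k: int = DEFAULT_K,
                   n_comp: int = 2,
                   variables: tuple[str, ...] = ("annt", "mtwa", "mtco")) -> CvResult:
    """Leave-one-out or h-block cross-validation of a transfer method.

    h-block withholds, for each test sample, the sample itself plus every
    site strictly within ``h`` km, so ``h=0`` reduces exactly to LOO.
    """
    method = method.lower()
    if method not in ("mat", "wapls"):
        raise ValidationError(f"unknown method {method!r}")
    if scheme not in ("loo", "h_block"):
        raise ValidationError(f"unknown scheme {scheme!r}")
    if h < 0:
        raise ValidationError("h must be >= 0")
    n = calib.features.shape[0]
    dist = site_distance_matrix(calib.coords)
    if scheme == "loo" or h == 0:
        exclude = np.eye(n, dtype=bool)
    else:
        exclude = dist < h
        np.fill_diagonal(exclude, True)
    y = calib.climate[list(variables)].to_numpy()
    preds = np.full((n, len(variables)), np.nan)
    dropped = 0
    if method == "mat":
        model = MATRegressor(k=k, scd_max=np.inf).fit(calib.features, y)
        try:
            out = model.predict_detailed(calib.features, exclude=exclude)
            preds = out["estimate_all"]
        except ValidationError:
            for i in range(n):
                if exclude[i].all():
                    dropped += 1
                    continue
                out = model.predict_detailed(calib.features[i:i + 1],
                                             exclude=exclude[i:i + 1])
                preds[i] = out["estimate_all"][0]
    else:
        for i in range(n):
            pool = ~exclude[i]
            if pool.sum() < n_comp + 2:
                dropped += 1
                continue
            for j, v in enumerate(variables):
                m = WAPLSRegressor(n_components=n_comp).fit(
                    calib.features[pool], y[pool, j])
                preds[i, j] = m.predict(calib.features[i:i + 1])[0]
    if dropped:
        logger.warning("cross_validate: %d samples dropped (empty pools)", dropped)
    r2, rmsep = {}, {}
    for j, v in enumerate(variables):
        ok = ~np.isnan(preds[:, j])
        r = np.corrcoef(preds[ok, j], y[ok, j])[0, 1]
        r2[v] = float(r**2)
        rmsep[v] = float(np.sqrt(np.mean((preds[ok, j] - y[ok, j]) ** 2)))
    table = pd.DataFrame(preds, columns=[f"pred_{v}" for v in variables])
    for j, v in enumerate(variables):
        table[f"obs_{v}"] = y[:, j]
    return CvResult(method=method.upper() if method == "mat" else "WAPLS",
                    scheme="loo" if (scheme == "loo" or h == 0) else "h_block",
                    h=float(h), r2=r2, rmsep=rmsep, predictions=table,
                    n_dropped=dropped)


def hblock_median_scd(calib: CalibrationSet, h: float) -> float:
    """Median nearest-analogue SCD over the calibration set at radius h."""
    d = pairwise_scd(calib.features, calib.features, normalize=True)
    dist = site_distance_matrix(calib.coords)
    excl = dist < h
    np.fill_diagonal(excl, True)
    d = np.where(excl, np.inf, d)
    mins = d.min(axis=1)
    return float(np.median(mins[np.isfinite(mins)]))


def select_h(calib: CalibrationSet, fossil_min_scds: np.ndarray,
             h_grid: np.ndarray | None = None) -> tuple[float, pd.DataFrame]:
    """Pick the h-block radius matching the fossil analogue quality.

    The changing-h experiment records, per h, the median nearest-analogue
    SCD within the calibration set; h* is the smallest h whose median
    meets or exceeds the median fossil nearest-analogue SCD.  If the
    fossil median is never reached, the largest h is returned with a
    warning.
    """
    fossil_min_scds = np.asarray(fossil_min_scds, dtype=float)
    if fossil_min_scds.size == 0:
        raise ValidationError("empty fossil SCD list")
    if h_grid is None:
        h_grid = np.arange(0.0, 1001.0, 100.0)
    h_grid = np.asarray(h_grid, dtype=float)
    target = float(np.median(fossil_min_scds))
    medians = np.array([hblock_median_scd(calib, h) for h in h_grid])
    curve = pd.DataFrame({"h_km": h_grid, "median_scd": medians})
    hit = np.nonzero(medians >= target)[0]
    if hit.size == 0:
        logger.warning("select_h: fossil median SCD %.4f above all curve values; "
                       "using h=%.0f km", target, h_grid[-1])
        return float(h_grid[-1]), curve
    return float(h_grid[hit[0]]), curve


# ----------------------------------------------------------- significance

@dataclass
class SignificanceResult:
    observed_var: float
    null_var: np.ndarray
    quantile_threshold: float
    threshold_value: float
    passed: bool
    variable: str = ""


def significance_test(fossil_assemblages: np.ndarray, recon: np.ndarray,
                      calib: CalibrationSet, variable: str = "mtco",
                      method: str = "mat", k: int = DEFAULT_K,
                      n_rand: int = 999, quantile: float = 0.842,
                      seed: int | None = None,
                      n_comp: int = 2) -> SignificanceResult:
    """Random-transfer-function significance test for one reconstruction.

    The observed statistic is the fraction of fossil-assemblage variance
    explained by the reconstructed series as the sole RDA constraint.
    Null reconstructions are built by training the same transfer method
    on variables drawn uniformly over the calibration climate range.  For
    MAT the analogue weights do not depend on the trained variable, so
    null reconstructions are the fixed weight matrix applied to the
    random variable — identical to retraining, at a fraction of the cost.
    """
    if n_rand < 1:
        raise ValidationError("n_rand must be >= 1")
    if not 0 < quantile <= 1:
        raise ValidationError("quantile must be in (0, 1]")
    rng = np.random.default_rng(seed)
    F = np.asarray(fossil_assemblages, dtype=float)
    recon = np.asarray(recon, dtype=float)
    if recon.shape[0] != F.shape[0]:
        raise ValidationError("reconstruction not aligned to fossil samples")

    # closed form for a single constraint: ||x_c' Y_c||^2 / (x_c'x_c) over
    # total inertia equals the RDA constrained-variance fraction
    Fc = F - F.mean(axis=0)
    sd = Fc.std(axis=0, ddof=1)
    Fc = Fc[:, sd > 0] / sd[sd > 0]
    total = float(np.sum(Fc**2))

    def explained(series: np.ndarray) -> float:
        xc = series - series.mean()
        ss = float(xc @ xc)
        if ss == 0.0 or total == 0.0:
            return 0.0
        proj = xc @ Fc
        return float(np.sum(proj**2) / ss / total)

    observed = explained(recon)
    lo = float(calib.climate[variable].min())
    hi = float(calib.climate[variable].max())
    null = np.empty(n_rand)
    if method.lower() == "mat":
        model = MATRegressor(k=k, scd_max=np.inf).fit(
            calib.features, np.zeros(calib.features.shape[0]))
        out = model.predict_detailed(F)
        W = np.zeros((F.shape[0], calib.features.shape[0]))
        for i in range(F.shape[0]):
            di = out["analogue_scd"][i]
            idx = out["analogue_idx"][i]
            if di[0] == 0.0:
                zero = di == 0.0
                W[i, idx[zero]] = 1.0 / zero.sum()
            else:
                w = 1.0 / di
                W[i, idx] = w / w.sum()
        for b in range(n_rand):
            env = rng.uniform(lo, hi, size=calib.features.shape[0])
            null[b] = explained(W @ env)
    else:
        for b in range(n_rand):
            env = rng.uniform(lo, hi, size=calib.features.shape[0])
            m = WAPLSRegressor(n_components=n_comp).fit(calib.features, env)
            null[b] = explained(m.predict(F))
    if quantile >= 1.0:
        thresh = float(null.max())
    else:
        thresh = float(np.quantile(null, quantile))
    return SignificanceResult(
        observed_var=observed, null_var=null, quantile_threshold=quantile,
        threshold_value=thresh, passed=bool(observed > thresh), variable=variable,
    )
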