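"""The space-for-time unmixing engine.

Inside a small moving window, cloud fractional cover y is modelled as a
linear mixture of land-cover class fractions: y_i = sum_j beta_j x_ij. The
regression is never run on the raw composition matrix X — compositional
closure makes it rank-deficient and subset-dependent — but on an SVD-reduced
design: X is column-centered, decomposed as (X - M) = U D V^t, and only the
dimensions carrying variance are kept (all of it, up to floating-point
rank), giving Z = (X - M) V_z. An ordinary least-squares fit of y on Z
(with intercept) then predicts the cloud fraction of a "dummy pixel" of
pure class composition through the same transform, and the difference of
two pure-class predictions is the transition effect, with an uncertainty
propagated from the coefficient covariance:

    sigma_{A->B} = sqrt(sigma_A^2 + sigma_B^2 - 2 sigma_AB),
    Sigma       = Z_p Var[beta] Z_p^t.

Windows must contain at least 60% valid pixels, at least 40% of which have
distinct compositions; failing windows, and degenerate designs, yield
missing cells with a reason code rather than exceptions, so a full-map run
always completes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cloudshift.grids import CloudGrid, DeltaMap, FractionGrid, MaskReason

__all__ = [
    "CompositionWindow",
    "PurePrediction",
    "ReducedDesign",
    "TransitionDelta",
    "UnmixFit",
    "extract_window",
    "fit_reduced_regression",
    "predict_pure_classes",
    "reduce_design",
    "run_space_for_time",
    "transition_delta",
]

#: Relative singular-value cutoff: dimensions with s > RTOL * s_max are kept,
#: which retains the full variance of the composition up to floating point.
SVD_RTOL = 1e-10

#: Fractions are rounded to this many decimals before testing distinctness,
#: so floating-point noise cannot make two equal compositions look distinct.
DISTINCT_DECIMALS = 6


@dataclass
class CompositionWindow:
    """Valid pixels of one moving window: composition rows and cloud values."""

    X: np.ndarray                  # (n, m) land-cover fractions
    y: np.ndarray                  # (n,) cloud fractions
    center: tuple[int, int]
    class_names: tuple[str, ...]
    valid: bool
    reason: MaskReason
    n_total: int                   # window_size ** 2

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class ReducedDesign:
    """Column-centered SVD reduction of a window's composition matrix."""

    column_means: np.ndarray       # M, (m,)
    V_z: np.ndarray                # (m, z) retained right singular vectors
    Z: np.ndarray                  # (n, z) reduced predictors
    singular_values: np.ndarray    # all singular values D
    z: int
    degenerate: bool = False


@dataclass
class UnmixFit:
    """OLS fit of cloud fraction on the reduced design (intercept first)."""

    beta: np.ndarray               # (z+1,)
    var_beta: np.ndarray           # (z+1, z+1)
    sigma2: float                  # residual variance RSS / (n - z - 1)
    dof: int


@dataclass
class PurePrediction:
    """Predicted cloud fraction of pure-class dummy pixels, with covariance."""

    classes: tuple[str, ...]
    y_p: np.ndarray                # (k,)
    Sigma: np.ndarray              # (k, k)

    def value(self, name: str) -> float:
        return float(self.y_p[self.classes.index(name)])


@dataclass
class TransitionDelta:
    """Full-transition cloud-fraction change A -> B with its uncertainty."""

    delta: float
    sigma: float


def _distinct_rows(X: np.ndarray) -> int:
    rounded = np.round(X, DISTINCT_DECIMALS)
    return np.unique(rounded, axis=0).shape[0]


def extract_window(fractions: FractionGrid, cloud_layer: np.ndarray,
                   center: tuple[int, int], window_size: int = 7,
                   water_class: str = "water", water_threshold: float = 0.5,
                   min_valid_frac: float = 0.6,
                   min_distinct_frac: float = 0.4) -> CompositionWindow:
    """Collect the valid pixels of one window and judge its usability.

    A pixel is valid when its cloud value and composition are observed and
    it is not water-dominated (water fraction < ``water_threshold``; this
    buffers coastlines, where marine processes dominate cloud formation).
    The window is usable when valid pixels make up at least
    ``min_valid_frac`` of the window and at least ``min_distinct_frac`` of
    the valid rows carry distinct compositions.
    """
    r, c = center
    h = window_size // 2
    n_lat, n_lon = fractions.shape
    n_total = window_size * window_size
    names = fractions.class_names
    empty = np.empty((0, len(names)))
    if r < h or c < h or r + h >= n_lat or c + h >= n_lon:
        return CompositionWindow(empty, np.empty(0), center, names, False,
                                 MaskReason.EDGE, n_total)

    sl = (slice(r - h, r + h + 1), slice(c - h, c + h + 1))
    X = fractions.fractions[(slice(None),) + sl].reshape(len(names), -1).T
    y = np.asarray(cloud_layer[sl], dtype=float).ravel()
    ok = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if water_class in names:
        ok &= X[:, names.index(water_class)] < water_threshold
    X, y = X[ok], y[ok]

    if X.shape[0] < min_valid_frac * n_total:
        return CompositionWindow(X, y, center, names, False,
                                 MaskReason.TOO_FEW_VALID, n_total)
    if _distinct_rows(X) < min_distinct_frac * X.shape[0]:
        return CompositionWindow(X, y, center, names, False,
                                 MaskReason.TOO_FEW_DISTINCT, n_total)
    return CompositionWindow(X, y, center, names, True, MaskReason.OK, n_total)


def reduce_design(X: np.ndarray, rtol: float = SVD_RTOL) -> ReducedDesign:
    """Column-center X and keep every SVD dimension that carries variance.

    For compositional rows the centered matrix has rank at most m - 1
    (closure removes one dimension); identical rows give rank 0, flagged
    degenerate so the caller can skip the window.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to reduce a design")
    M = X.mean(axis=0)
    Xc = X - M
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fractions are O(1), so a centered matrix whose largest singular value
    # is at rounding level means all rows coincide
    if s.size == 0 or s[0] <= 1e-12:
        keep = np.zeros_like(s, dtype=bool)
    else:
        keep = s > rtol * s[0]
    z = int(keep.sum())
    V_z = Vt[keep].T
    Z = Xc @ V_z
    return ReducedDesign(M, V_z, Z, s, z, degenerate=(z == 0))


def fit_reduced_regression(design: ReducedDesign, y: np.ndarray) -> UnmixFit:
    """OLS of y on the reduced design, intercept prepended.

    Coefficient covariance is the homoscedastic estimator
    sigma^2 (Z^t Z)^{-1} with sigma^2 = RSS / (n - z - 1).
    """
    y = np.asarray(y, dtype=float)
    n, z = design.Z.shape
    if design.degenerate:
        raise ValueError("degenerate design (z = 0); window must be skipped")
    if n <= z + 1:
        raise ValueError(f"insufficient degrees of freedom: n={n}, z={z}")
    Za = np.column_stack([np.ones(n), design.Z])
    A = Za.T @ Za
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular normal equations") from exc
    beta = A_inv @ (Za.T @ y)
    resid = y - Za @ beta
    dof = n - z - 1
    sigma2 = float(resid @ resid) / dof
    return UnmixFit(beta, sigma2 * A_inv, sigma2, dof)


def predict_pure_classes(fit: UnmixFit, design: ReducedDesign,
                         classes: Sequence[str],
                         legend: Sequence[str]) -> PurePrediction:
    """Predict the cloud fraction of single-class dummy pixels.

    P holds one one-hot row per requested class (in the full legend's
    coordinates); it is centered on the window's column means, projected
    onto the retained singular vectors, and pushed through the fit:
    y_p = Z_p beta, Sigma = Z_p Var[beta] Z_p^t.
    """
    legend = list(legend)
    idx = []
    for name in classes:
        if name not in legend:
            raise KeyError(f"unknown land-cover class {name!r}")
        idx.append(legend.index(name))
    P = np.zeros((len(idx), len(legend)))
    P[np.arange(len(idx)), idx] = 1.0
    Zp = (P - design.column_means) @ design.V_z
    Zpa = np.column_stack([np.ones(len(idx)), Zp])
    y_p = Zpa @ fit.beta
    Sigma = Zpa @ fit.var_beta @ Zpa.T
    return PurePrediction(tuple(classes), y_p, Sigma)


def transition_delta(pred: PurePrediction, from_class: str,
                     to_class: str) -> TransitionDelta:
    """Effect of a full A -> B transition: delta = y_B - y_A.

    The uncertainty subtracts twice the prediction covariance — both pure
    predictions come from the same local fit, so their errors are strongly
    correlated; a floating-point negative radicand is clamped to zero.
    """
    a = pred.classes.index(from_class)
    b = pred.classes.index(to_class)
    delta = float(pred.y_p[b] - pred.y_p[a])
    radicand = pred.Sigma[a, a] + pred.Sigma[b, b] - 2.0 * pred.Sigma[a, b]
    return TransitionDelta(delta, float(np.sqrt(max(0.0, radicand))))


def _window_masks(fractions: FractionGrid, clouds: np.ndarray,
                  water_idx: int | None, water_threshold: float) -> np.ndarray:
    """(n_months, n_lat, n_lon) per-pixel validity."""
    frac_ok = np.all(np.isfinite(fractions.fractions), axis=0)
    if water_idx is not None:
        frac_ok &= fractions.fractions[water_idx] < water_threshold
    return np.isfinite(clouds) & frac_ok[None, :, :]


def run_space_for_time(fractions: FractionGrid, clouds: CloudGrid,
                       transitions: Sequence[tuple[str, str]],
                       window_size: int = 7,
                       water_class: str = "water", water_threshold: float = 0.5,
                       min_valid_frac: float = 0.6,
                       min_distinct_frac: float = 0.4,
                       months: Sequence[int] | None = None,
                       rtol: float = SVD_RTOL) -> DeltaMap:
    """Apply the windowed unmixing to every cell and monthly layer.

    ``months`` selects 1-based calendar months (default: all 12). Each
    monthly output layer maps the full-transition effect at every interior
    window center; cells without an estimate carry a
    :class:`~cloudshift.grids.MaskReason` code. The composition does not
    change across months, so the SVD reduction is computed once per center
    and reused for every month sharing the same valid-pixel set.
    """
    if fractions.shape != clouds.shape or not (
            np.array_equal(fractions.lat, clouds.lat)
            and np.array_equal(fractions.lon, clouds.lon)):
        raise ValueError("fraction and cloud grids are not aligned")
    names = fractions.class_names
    needed = sorted({c for pair in transitions for c in pair})
    for c in needed:
        if c not in names:
            raise KeyError(f"transition class {c!r} not in legend")
    t_idx = [(needed.index(a), needed.index(b)) for a, b in transitions]

    month_list = list(months) if months is not None else list(range(1, 13))
    n_months = len(month_list)
    n_lat, n_lon = fractions.shape
    h = window_size // 2
    n_total = window_size * window_size

    shape = (n_months, len(transitions), n_lat, n_lon)
    delta = np.full(shape, np.nan)
    sigma = np.full(shape, np.nan)
    reason = np.full(shape, MaskReason.EDGE, dtype=np.uint8)

    water_idx = names.index(water_class) if water_class in names else None
    cloud_sel = clouds.clouds[[m - 1 for m in month_list]]
    pix_ok = _window_masks(fractions, cloud_sel, water_idx, water_threshold)
    frac_flat = fractions.fractions.reshape(len(names), -1)

    # Dummy-pixel rows in raw composition coordinates, one per needed class.
    P = np.zeros((len(needed), len(names)))
    for k, c in enumerate(needed):
        P[k, names.index(c)] = 1.0

    for r in range(h, n_lat - h):
        for c in range(h, n_lon - h):
            rows = np.arange(r - h, r + h + 1)
            cols = np.arange(c - h, c + h + 1)
            flat = (rows[:, None] * n_lon + cols[None, :]).ravel()
            masks = pix_ok[:, r - h:r + h + 1, c - h:c + h + 1].reshape(n_months, -1)

            cache: dict[bytes, tuple] = {}
            for mi in range(n_months):
                mask = masks[mi]
                key = mask.tobytes()
                if key not in cache:
                    cache[key] = _prepare_design(frac_flat, flat, mask, P,
                                                 n_total, min_valid_frac,
                                                 min_distinct_frac, rtol)
                prep = cache[key]
                if isinstance(prep, MaskReason):
                    reason[mi, :, r, c] = prep
                    continue
                Za, A_inv, H, Zpa, S0, sel, z, n = prep
                y = cloud_sel[mi].ravel()[flat[sel]]
                beta = H @ y
                resid = y - Za @ beta
                sigma2 = float(resid @ resid) / (n - z - 1)
                y_p = Zpa @ beta
                Sigma = sigma2 * S0
                for ti, (ia, ib) in enumerate(t_idx):
                    d = float(y_p[ib] - y_p[ia])
                    rad = Sigma[ia, ia] + Sigma[ib, ib] - 2.0 * Sigma[ia, ib]
                    delta[mi, ti, r, c] = d
                    sigma[mi, ti, r, c] = np.sqrt(max(0.0, rad))
                    reason[mi, ti, r, c] = MaskReason.OK

    return DeltaMap(delta, sigma, reason, tuple(tuple(p) for p in transitions),
                    fractions.lat, fractions.lon, window_size)


def _prepare_design(frac_flat: np.ndarray, flat_idx: np.ndarray,
                    mask: np.ndarray, P: np.ndarray, n_total: int,
                    min_valid_frac: float, min_distinct_frac: float,
                    rtol: float):
    """Validity checks plus every month-independent matrix for one window.

    Returns a MaskReason on rejection, otherwise the cached tuple
    (Za, A_inv, H, Zpa, S0, sel, z, n) where H maps y to beta and
    S0 = Z_pa (Z_a^t Z_a)^{-1} Z_pa^t scales by sigma^2 into the prediction
    covariance.
    """
    sel = np.flatnonzero(mask)
    n = sel.size
    if n < min_valid_frac * n_total:
        return MaskReason.TOO_FEW_VALID
    X = frac_flat[:, flat_idx[sel]].T
    if _distinct_rows(X) < min_distinct_frac * n:
        return MaskReason.TOO_FEW_DISTINCT
    design = reduce_design(X, rtol)
    if design.degenerate:
        return MaskReason.DEGENERATE
    z = design.z
    if n <= z + 1:
        return MaskReason.LOW_DOF
    Za = np.column_stack([np.ones(n), design.Z])
    A = Za.T @ Za
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return MaskReason.DEGENERATE
    H = A_inv @ Za.T
    Zp = (P - design.column_means) @ design.V_z
    Zpa = np.column_stack([np.ones(P.shape[0]), Zp])
    S0 = Zpa @ A_inv @ Zpa.T
    return Za, A_inv, H, Zpa, S0, sel, z, n
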