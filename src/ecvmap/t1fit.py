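"""Pixel-wise three-parameter inversion-recovery T1 fitting.

The signal of a magnitude-detected inversion-recovery image acquired at
inversion time ``TI`` is modelled as ``|A - B * exp(-TI / T1*)|``.  The
apparent recovery constant ``T1*`` is converted to T1 with the
Look-Locker correction ``T1 = T1* * (B/A - 1)``.

The per-pixel non-linear least-squares problem is solved with downhill
simplex (Nelder-Mead) polishing started from a vectorised coarse search
that enumerates signal-polarity hypotheses on a T1* grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "MolliSeries",
    "T1MapResult",
    "PixelFit",
    "ir_signal",
    "fit_pixel",
    "fit_map",
    "look_locker_correct",
    "synthesize_image",
    "initial_t1_estimate",
]

# Acceptance bounds for a fit to be considered physiological / usable.
T1_MIN_MS = 1.0
T1_MAX_MS = 5000.0
BA_RATIO_MIN = 1.0
BA_RATIO_MAX = 3.0

#: Canonical multi-start T1* seeds (ms) for the simplex polish.
DEFAULT_T1_STAR_STARTS = (150.0, 400.0, 800.0, 1500.0)


@dataclass
class MolliSeries:
    """A stack of magnitude images, one per inversion time.

    Parameters
    ----------
    images : ndarray, shape (n_ti, nrow, ncol)
        Magnitude images in acquisition order.
    ti_values : ndarray, shape (n_ti,)
        Inversion time of each image in milliseconds.
    pixel_spacing : tuple of float
        In-plane pixel spacing (row, col) in millimetres.
    contrast_phase : {"pre", "post"}
        Whether the series was acquired before or after contrast.
    meta : dict
        Free-form acquisition tags (heart rate, protocol variant, ...).
    """

    images: np.ndarray
    ti_values: np.ndarray
    pixel_spacing: tuple[float, float] = (1.9, 1.9)
    contrast_phase: str = "pre"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.ti_values = np.asarray(self.ti_values, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_ti, nrow, ncol) stack")
        if self.ti_values.ndim != 1 or len(self.ti_values) != len(self.images):
            raise ValueError(
                f"need exactly one TI per image: got {len(self.ti_values)} TIs "
                f"for {len(self.images)} images"
            )
        if np.any(self.ti_values <= 0):
            raise ValueError("all inversion times must be > 0 ms")
        if len(np.unique(self.ti_values)) != len(self.ti_values):
            raise ValueError("inversion times must be distinct")
        if self.contrast_phase not in ("pre", "post"):
            raise ValueError("contrast_phase must be 'pre' or 'post'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def n_images(self) -> int:
        return self.images.shape[0]

    def longest_ti_index(self) -> int:
        return int(np.argmax(self.ti_values))

    def shortest_ti_index(self) -> int:
        return int(np.argmin(self.ti_values))

    def replace_images(self, images: np.ndarray) -> "MolliSeries":
        """Return a copy of the series with a new image stack."""
        return MolliSeries(
            images=np.asarray(images, dtype=float),
            ti_values=self.ti_values.copy(),
            pixel_spacing=self.pixel_spacing,
            contrast_phase=self.contrast_phase,
            meta=dict(self.meta),
        )


@dataclass
class T1MapResult:
    """Per-pixel fit parameters and quality maps.

    ``t1_map = t1_star_map * (b_map / a_map - 1)`` wherever ``fit_ok_mask``;
    ``rss_map`` is the sum of squared residuals of the measured signals
    against the fitted recovery curve (a goodness-of-fit map).
    """

    a_map: np.ndarray
    b_map: np.ndarray
    t1_star_map: np.ndarray
    t1_map: np.ndarray
    rss_map: np.ndarray
    fit_ok_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t1_map.shape


class PixelFit(NamedTuple):
    a: float
    b: float
    t1_star: float
    rss: float
    ok: bool


def ir_signal(ti, a, b, t1_star):
    """Magnitude inversion-recovery signal ``|A - B exp(-TI/T1*)|``."""
    return np.abs(a - b * np.exp(-np.asarray(ti, dtype=float) / t1_star))


def look_locker_correct(a, b, t1_star):
    """Convert the apparent T1* to T1 via ``T1 = T1* (B/A - 1)``.

    Works elementwise on arrays.  Pixels with ``A <= 0`` yield NaN; callers
    flag them not-ok.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t1_star = np.asarray(t1_star, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(a > 0, t1_star * (b / a - 1.0), np.nan)
    if t1.ndim == 0:
        return float(t1)
    return t1


def _coarse_search(
    signals: np.ndarray,
    ti_values: np.ndarray,
    t1_star_grid: np.ndarray,
    n_keep: int = 3,
):
    """Vectorised polarity-enumeration search over a T1* grid.

    For every candidate T1* and every polarity split (the ``k`` shortest-TI
    samples assumed on the still-inverted branch), solve the linear
    least-squares problem for (A, B) on polarity-restored data, then score
    the candidate with the true magnitude-model residual.

    Parameters
    ----------
    signals : ndarray, shape (n_pix, n_ti)
    ti_values : ndarray, shape (n_ti,)
    t1_star_grid : ndarray
        Candidate T1* values (ms).
    n_keep : int
        Number of best distinct candidates to return per pixel.

    Returns
    -------
    params : ndarray, shape (n_pix, n_keep, 3)
        Best (A, B, T1*) candidates, ordered by increasing residual.
    rss : ndarray, shape (n_pix, n_keep)
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n_pix, n_ti = signals.shape
    order = np.argsort(ti_values)
    ti_sorted = ti_values[order]
    s_sorted = signals[:, order]

    best_rss = np.full((n_pix, n_keep), np.inf)
    best_par = np.zeros((n_pix, n_keep, 3))

    for t1s in t1_star_grid:
        x = np.exp(-ti_sorted / t1s)  # (n_ti,)
        sx = x.sum()
        sxx = x @ x
        det = n_ti * sxx - sx * sx
        if abs(det) < 1e-12:
            continue
        for k in range(n_ti + 1):
            sign = np.ones(n_ti)
            sign[:k] = -1.0
            y = s_sorted * sign  # polarity-restored data, (n_pix, n_ti)
            sy = y.sum(axis=1)
            sxy = y @ x
            # least squares for y ~ A - B x
            a = (sxx * sy - sx * sxy) / det
            b = (sx * sy - n_ti * sxy) / det
            model = np.abs(a[:, None] - b[:, None] * x[None, :])
            rss = np.sum((s_sorted - model) ** 2, axis=1)
            worst = best_rss[:, -1]
            improve = rss < worst
            if not np.any(improve):
                continue
            idx = np.nonzero(improve)[0]
            cand = np.stack(
                [a[idx], b[idx], np.full(idx.size, t1s)], axis=1
            )
            # insert candidate into the sorted keep-list of each pixel
            sub_rss = np.concatenate(
                [best_rss[idx], rss[idx, None]], axis=1
            )
            sub_par = np.concatenate(
                [best_par[idx], cand[:, None, :]], axis=1
            )
            ordr = np.argsort(sub_rss, axis=1)[:, :n_keep]
            best_rss[idx] = np.take_along_axis(sub_rss, ordr, axis=1)
            best_par[idx] = np.take_along_axis(
                sub_par, ordr[:, :, None], axis=1
            )
    return best_par, best_rss


def _default_t1_star_grid() -> np.ndarray:
    return np.geomspace(20.0, 5000.0, 60)


def _rss_batch(params: np.ndarray, signals: np.ndarray,
               ti_values: np.ndarray) -> np.ndarray:
    """Vectorised objective: params (N, 3), signals (N, n_ti) -> rss (N,)."""
    a = params[:, 0:1]
    b = params[:, 1:2]
    t1s = params[:, 2:3]
    bad = (t1s <= 1e-6).ravel()
    safe = np.where(t1s > 1e-6, t1s, 1.0)
    with np.errstate(over="ignore", invalid="ignore"):
        model = np.abs(a - b * np.exp(-ti_values[None, :] / safe))
        rss = np.einsum("ij,ij->i", signals - model, signals - model)
    rss[bad | ~np.isfinite(rss)] = np.inf
    return rss


def _nelder_mead_batch(
    signals: np.ndarray,
    ti_values: np.ndarray,
    x0: np.ndarray,
    max_iter: int = 400,
    frtol: float = 1e-12,
    xrtol: float = 1e-8,
):
    """Downhill-simplex minimisation run simultaneously for many pixels.

    Standard Nelder-Mead (reflection / expansion / contraction / shrink
    with the usual 1, 2, 0.5, 0.5 coefficients) where every step is a
    masked vectorised update over all N pixel problems.  Initial simplex:
    ``x0`` perturbed by 5% per coordinate (0.00025 absolute at zeros), as
    in common simplex implementations.

    Returns ``(x_best (N, 3), f_best (N,))``.
    """
    n_pix = x0.shape[0]
    ndim = 3
    simplex = np.repeat(x0[:, None, :], ndim + 1, axis=1)
    for d in range(ndim):
        col = simplex[:, d + 1, d]
        simplex[:, d + 1, d] = np.where(col != 0, col * 1.05, 0.00025)
    fvals = np.stack(
        [_rss_batch(simplex[:, v], signals, ti_values)
         for v in range(ndim + 1)], axis=1
    )

    for _ in range(max_iter):
        order = np.argsort(fvals, axis=1)
        fvals = np.take_along_axis(fvals, order, axis=1)
        simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)

        fbest = fvals[:, 0]
        fspread = fvals[:, -1] - fbest
        xspread = np.max(
            np.abs(simplex - simplex[:, :1, :]).max(axis=1)
            / (np.abs(simplex[:, 0, :]) + 1e-12),
            axis=1,
        )
        active = ~(
            (fspread <= frtol * (1.0 + np.abs(fbest))) & (xspread <= xrtol)
        )
        if not active.any():
            break

        centroid = simplex[:, :ndim].mean(axis=1)
        worst = simplex[:, ndim]
        xr = 2.0 * centroid - worst
        fr = _rss_batch(xr, signals, ti_values)

        new_pt = xr.copy()
        new_f = fr.copy()
        # expansion where the reflection is a new best
        expand = active & (fr < fvals[:, 0])
        if expand.any():
            xe = 3.0 * centroid - 2.0 * worst
            fe = _rss_batch(xe, signals, ti_values)
            better = expand & (fe < fr)
            new_pt[better] = xe[better]
            new_f[better] = fe[better]
        accept = active & (fr < fvals[:, ndim - 1])
        # contraction where the reflection is no better than second-worst
        contract = active & ~accept
        shrink = np.zeros(n_pix, dtype=bool)
        if contract.any():
            outside = fr < fvals[:, ndim]
            xc = np.where(
                outside[:, None],
                centroid + 0.5 * (xr - centroid),
                centroid + 0.5 * (worst - centroid),
            )
            fc = _rss_batch(xc, signals, ti_values)
            good = contract & (fc < np.minimum(fr, fvals[:, ndim]))
            new_pt[good] = xc[good]
            new_f[good] = fc[good]
            accept = accept | good
            shrink = contract & ~good

        replace = (expand & (new_f < fvals[:, ndim])) | accept
        simplex[replace, ndim] = new_pt[replace]
        fvals[replace, ndim] = new_f[replace]

        if shrink.any():
            best = simplex[:, :1, :]
            simplex[shrink, 1:, :] = (
                best[shrink] + 0.5 * (simplex[shrink, 1:, :] - best[shrink])
            )
            for v in range(1, ndim + 1):
                fvals[shrink, v] = _rss_batch(
                    simplex[shrink, v], signals[shrink], ti_values
                )

    order = np.argsort(fvals, axis=1)
    fvals = np.take_along_axis(fvals, order, axis=1)
    simplex = np.take_along_axis(simplex, order[:, :, None], axis=1)
    return simplex[:, 0, :], fvals[:, 0]


def _objective(params, signal, ti_values):
    a, b, t1s = params
    if t1s <= 1e-6:
        return np.inf
    resid = signal - np.abs(a - b * np.exp(-ti_values / t1s))
    return float(resid @ resid)


def _polish(signal, ti_values, start, maxiter=2000):
    res = minimize(
        _objective,
        np.asarray(start, dtype=float),
        args=(signal, ti_values),
        method="Nelder-Mead",
        options={
            "maxiter": maxiter,
            "xatol": 1e-7,
            "fatol": 1e-13,
        },
    )
    return res.x, float(res.fun)


def fit_pixel(
    signal: Sequence[float],
    ti_values: Sequence[float],
    multi_start: bool = True,
    t1_star_starts: Sequence[float] = DEFAULT_T1_STAR_STARTS,
) -> PixelFit:
    """Fit ``|A - B exp(-TI/T1*)|`` to one pixel's samples.

    Downhill-simplex minimisation of the sum of squared residuals, started
    from the best candidates of a coarse polarity-enumeration grid search
    and (if ``multi_start``) from canonical T1* seeds with ``A = max(s)``,
    ``B = 2A``.  The lowest-residual solution is returned.

    Returns
    -------
    PixelFit
        ``(a, b, t1_star, rss, ok)``; ``ok`` is False for degenerate or
        non-physiological fits (non-finite input, all-zero signal, T1 or
        B/A outside acceptance bounds).
    """
    signal = np.asarray(signal, dtype=float)
    ti_values = np.asarray(ti_values, dtype=float)
    if signal.shape != ti_values.shape or signal.ndim != 1:
        raise ValueError("signal and ti_values must be 1-D and aligned")
    if signal.size < 4:
        raise ValueError("need at least 4 samples for a 3-parameter fit")
    if len(np.unique(ti_values)) != len(ti_values):
        raise ValueError("inversion times must be distinct")
    if not np.all(np.isfinite(signal)):
        return PixelFit(np.nan, np.nan, np.nan, np.inf, False)
    if np.all(signal == 0):
        return PixelFit(0.0, 0.0, np.nan, 0.0, False)

    starts = []
    cand_par, _ = _coarse_search(signal[None, :], ti_values,
                                 _default_t1_star_grid())
    for j in range(cand_par.shape[1]):
        a, b, t1s = cand_par[0, j]
        if np.isfinite(t1s) and t1s > 0:
            starts.append((a, b, t1s))
    if multi_start:
        a0 = float(np.max(signal))
        starts.extend((a0, 2.0 * a0, t1s) for t1s in t1_star_starts)

    best = None
    for start in starts:
        x, rss = _polish(signal, ti_values, start)
        if best is None or rss < best[1]:
            best = (x, rss)
    (a, b, t1s), rss = best
    ok = _fit_ok(a, b, t1s)
    return PixelFit(float(a), float(b), float(t1s), rss, bool(ok))


def _fit_ok(a, b, t1_star):
    if not (np.isfinite(a) and np.isfinite(b) and np.isfinite(t1_star)):
        return False
    if a <= 0 or t1_star <= 0:
        return False
    ratio = b / a
    if not (BA_RATIO_MIN <= ratio <= BA_RATIO_MAX):
        return False
    t1 = t1_star * (ratio - 1.0)
    return T1_MIN_MS <= t1 <= T1_MAX_MS


def fit_map(
    series: MolliSeries,
    mask: np.ndarray | None = None,
    signal_floor: float = 0.0,
    multi_start: bool = False,
) -> T1MapResult:
    """Pixel-wise three-parameter fit of a whole MOLLI series.

    Parameters
    ----------
    series : MolliSeries
    mask : ndarray of bool, optional
        Restrict fitting to these pixels; others are flagged not-ok.
    signal_floor : float
        Pixels whose maximum signal over all TIs is <= this value are
        skipped (flagged not-ok).  Speeds up maps with empty background.
    multi_start : bool
        Forwarded to :func:`fit_pixel`; the default relies on the coarse
        grid initialisation only, which is faster and matches the
        multi-start result on well-posed pixels.

    Never aborts on single-pixel failures; failures are flagged in
    ``fit_ok_mask``.
    """
    nrow, ncol = series.shape
    n_pix = nrow * ncol
    sig = series.images.reshape(series.n_images, n_pix).T  # (n_pix, n_ti)
    ti = series.ti_values

    a = np.zeros(n_pix)
    b = np.zeros(n_pix)
    t1s = np.full(n_pix, np.nan)
    rss = np.zeros(n_pix)
    ok = np.zeros(n_pix, dtype=bool)

    finite = np.all(np.isfinite(sig), axis=1)
    peak = np.where(finite, np.max(np.where(np.isfinite(sig), sig, 0), axis=1), 0)
    todo = finite & (peak > signal_floor)
    if mask is not None:
        todo &= np.asarray(mask, dtype=bool).ravel()
    # not-fitted pixels synthesize as their peak signal
    a[~todo] = peak[~todo]

    idx = np.nonzero(todo)[0]
    if idx.size:
        sub = np.ascontiguousarray(sig[idx])
        cand_par, _ = _coarse_search(sub, ti, _default_t1_star_grid())
        starts = [cand_par[:, j, :] for j in range(cand_par.shape[1])]
        if multi_start:
            a0 = np.max(sub, axis=1)
            for t1_seed in DEFAULT_T1_STAR_STARTS:
                starts.append(
                    np.stack([a0, 2 * a0, np.full(idx.size, t1_seed)], axis=1)
                )
        best_x = None
        best_f = None
        # batched downhill simplex: one vectorised run per start
        for x0 in starts:
            x, f = _nelder_mead_batch(sub, ti, np.ascontiguousarray(x0))
            if best_x is None:
                best_x, best_f = x, f
            else:
                better = f < best_f
                best_x[better] = x[better]
                best_f[better] = f[better]
        a[idx] = best_x[:, 0]
        b[idx] = best_x[:, 1]
        t1s[idx] = best_x[:, 2]
        rss[idx] = best_f
        ok[idx] = [
            _fit_ok(best_x[r, 0], best_x[r, 1], best_x[r, 2])
            for r in range(idx.size)
        ]
        # failed fits can land on huge (A, B) pairs that nearly cancel;
        # replace them with the bounded peak signal so downstream synthetic
        # images stay well-scaled
        bad = idx[~ok[idx]]
        a[bad] = peak[bad]
        b[bad] = 0.0
        t1s[bad] = np.nan

    a = a.reshape(nrow, ncol)
    b = b.reshape(nrow, ncol)
    t1s = t1s.reshape(nrow, ncol)
    rss = rss.reshape(nrow, ncol)
    ok = ok.reshape(nrow, ncol)
    t1 = np.where(ok, look_locker_correct(a, b, t1s), np.nan)
    return T1MapResult(
        a_map=a, b_map=b, t1_star_map=t1s, t1_map=t1, rss_map=rss,
        fit_ok_mask=ok,
        meta={"ti_values": ti.tolist(), "contrast_phase": series.contrast_phase},
    )


def synthesize_image(result: T1MapResult, ti: float) -> np.ndarray:
    """Synthesize a motion-free image at inversion time ``ti``.

    Evaluates ``|A - B exp(-ti/T1*)|`` per pixel from the fitted maps; on
    not-ok pixels the fully-recovered value ``A`` is returned instead.
    """
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        img = np.abs(
            result.a_map - result.b_map * np.exp(-ti / result.t1_star_map)
        )
    return np.where(result.fit_ok_mask, img, result.a_map)


def initial_t1_estimate(
    series: MolliSeries,
    default_t1: float = 1000.0,
    t1_cap: float = T1_MAX_MS,
) -> T1MapResult:
    """Crude closed-form T1 estimate from the shortest- and longest-TI images.

    Assumes full recovery at the longest TI (``A = s(TI_max)``) and ideal
    inversion (``B = 2A``) and solves ``s(TI_min) = |A - B exp(-TI_min/T1)|``
    per pixel.  When ``s(TI_min) < s(TI_max)`` the short-TI sample is taken
    to be still inverted (``s = B exp(-TI/T1) - A``); otherwise the
    non-inverted branch is used.  Degenerate pixels fall back to
    ``default_t1``.  The estimate is flagged crude in ``meta`` — it is only
    intended to seed motion correction.
    """
    if series.n_images < 2:
        raise ValueError("need at least 2 images for the two-point estimate")
    i_min = series.shortest_ti_index()
    i_max = series.longest_ti_index()
    s_min = series.images[i_min]
    s_max = series.images[i_max]
    ti_min = series.ti_values[i_min]

    a = s_max
    b = 2.0 * s_max
    valid = a > 0
    t1 = np.full(series.shape, default_t1, dtype=float)

    with np.errstate(divide="ignore", invalid="ignore"):
        inverted = valid & (s_min < s_max)
        # inverted branch: s = B exp(-TI/T1) - A  ->  T1 = TI / ln(2A/(s+A))
        denom_inv = np.log(b / (s_min + a))
        ok_inv = inverted & (denom_inv > 0)
        t1 = np.where(ok_inv, ti_min / np.where(ok_inv, denom_inv, 1.0), t1)
        # non-inverted branch: s = A - B exp(-TI/T1) -> T1 = TI / ln(2A/(A-s))
        noninv = valid & ~inverted & (s_min < a)
        denom_non = np.log(b / np.where(noninv, a - s_min, 1.0))
        ok_non = noninv & (denom_non > 0)
        t1 = np.where(ok_non, ti_min / np.where(ok_non, denom_non, 1.0), t1)

    t1 = np.clip(t1, 1.0, t1_cap)
    # two-point model implies B = 2A, so T1* coincides with T1
    model = np.abs(
        a[None] - b[None] * np.exp(-series.ti_values[:, None, None] / t1[None])
    )
    rss = np.sum((series.images - model) ** 2, axis=0)
    return T1MapResult(
        a_map=a.astype(float),
        b_map=b.astype(float),
        t1_star_map=t1.copy(),
        t1_map=t1,
        rss_map=rss,
        fit_ok_mask=valid,
        meta={"crude": True, "method": "two-point min/max TI"},
    )
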