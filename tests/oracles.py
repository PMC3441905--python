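"""Independent brute-force oracles used by the test-suite only."""

import numpy as np


def grid_search_fit(signal, ti_values, t1_star_step=1.0, t1_star_max=5000.0):
    """Dense-grid oracle for the magnitude inversion-recovery fit.

    Enumerates T1* in steps of ``t1_star_step`` ms; for each T1* and each
    polarity split (the k shortest-TI samples assumed negative before
    magnitude detection) computes the exact linear least-squares (A, B)
    on polarity-restored data, then scores the candidate with the true
    magnitude-model residual.  Independent of the production fitter.

    Returns (a, b, t1_star, rss).
    """
    signal = np.asarray(signal, dtype=float)
    ti_values = np.asarray(ti_values, dtype=float)
    order = np.argsort(ti_values)
    ti = ti_values[order]
    s = signal[order]
    n = len(s)

    grid = np.arange(t1_star_step, t1_star_max + t1_star_step, t1_star_step)
    x = np.exp(-ti[None, :] / grid[:, None])  # (G, n)
    sx = x.sum(axis=1)
    sxx = np.einsum("ij,ij->i", x, x)
    det = n * sxx - sx * sx

    best = (np.nan, np.nan, np.nan, np.inf)
    for k in range(n + 1):
        sign = np.ones(n)
        sign[:k] = -1.0
        y = s * sign
        sy = y.sum()
        sxy = x @ y
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (sxx * sy - sx * sxy) / det
            b = (sx * sy - n * sxy) / det
        model = np.abs(a[:, None] - b[:, None] * x)
        rss = np.sum((s[None, :] - model) ** 2, axis=1)
        rss[~np.isfinite(rss)] = np.inf
        i = int(np.argmin(rss))
        if rss[i] < best[3]:
            best = (float(a[i]), float(b[i]), float(grid[i]), float(rss[i]))
    return best


def random_ir_pixels(n_pixels, ti_values, seed, noise_sd=0.02):
    """Seeded random magnitude-IR pixels with physiological parameters."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.5, 1.5, n_pixels)
    ratio = rng.uniform(1.7, 2.1, n_pixels)  # B/A around ideal inversion
    t1 = rng.uniform(200.0, 2000.0, n_pixels)  # corrected T1
    t1_star = t1 / (ratio - 1.0)
    b = ratio * a
    clean = np.abs(
        a[:, None] - b[:, None] * np.exp(-ti_values[None, :] / t1_star[:, None])
    )
    noisy = clean + rng.normal(0.0, noise_sd, clean.shape)
    return noisy, np.stack([a, b, t1_star], axis=1)
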