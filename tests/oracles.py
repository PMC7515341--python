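"""Independent brute-force oracles the tests compare the implementation against."""

import numpy as np
from scipy.optimize import minimize_scalar


def burg_stagewise_ls(x: np.ndarray, order: int) -> np.ndarray:
    """AR coefficients by numerically minimizing, at each lattice stage, the
    summed forward+backward squared prediction error over the reflection
    coefficient — an independent route to the same optimum Burg computes in
    closed form."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    ef, eb = x[1:].astype(float), x[:-1].astype(float)
    a = np.zeros(0)
    for _ in range(order):
        def cost(k, ef=ef, eb=eb):
            return float(np.sum((ef + k * eb) ** 2) + np.sum((eb + k * ef) ** 2))

        k = minimize_scalar(
            cost, bounds=(-1.0, 1.0), method="bounded", options={"xatol": 1e-13}
        ).x
        a = np.concatenate((a + k * a[::-1], (k,)))
        ef, eb = ef[1:] + k * eb[1:], eb[:-1] + k * ef[:-1]
    return a


def naive_entropy(image: np.ndarray, n_levels: int, log_base: float,
                  global_range: tuple) -> float:
    """Two-pass histogram + explicit -sum p log p, written independently of the
    vectorized implementation."""
    gmin, gmax = global_range
    counts = [0] * n_levels
    flat = np.asarray(image, dtype=float).ravel()
    for v in flat:
        if gmax == gmin:
            b = 0
        else:
            b = int((v - gmin) / (gmax - gmin) * n_levels)
            if b >= n_levels:
                b = n_levels - 1
            if b < 0:
                b = 0
        counts[b] += 1
    total = len(flat)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log(p)
    return h / np.log(log_base)


def simulate_ar(coefs, n: int, seed: int, burn_in: int = 200) -> np.ndarray:
    """Simulate x(t) = sum_j coefs[j] x(t-j-1) + u(t) with unit-variance noise."""
    rng = np.random.default_rng(seed)
    total = n + burn_in
    u = rng.normal(size=total)
    x = np.zeros(total)
    for t in range(total):
        acc = u[t]
        for j, c in enumerate(coefs):
            if t - j - 1 >= 0:
                acc += c * x[t - j - 1]
        x[t] = acc
    return x[burn_in:]
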