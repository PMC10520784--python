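"""Independent brute-force oracles, kept separate from the production code.

Each oracle is a direct, unoptimized transliteration of the defining
formula or algorithm it checks, written without reference to the
production implementation.
"""

from collections import deque

import numpy as np


def kendalls_w_bruteforce(series_set: np.ndarray) -> float:
    """Kendall's W computed symbol-by-symbol from its definition.

    Ranks each series over time (mid-ranks for ties), forms the
    per-timepoint rank sums R_i, their mean Rbar = (n+1)K/2, and returns
    (sum R_i^2 - n Rbar^2) / (K^2 (n^3 - n) / 12).
    """
    series = np.asarray(series_set, dtype=float)
    K, n = series.shape
    ranks = np.empty((K, n))
    for j in range(K):
        order = np.argsort(series[j], kind="stable")
        r = np.empty(n)
        i = 0
        while i < n:
            # group of tied values -> average rank
            k = i
            while k + 1 < n and series[j, order[k + 1]] == series[j, order[i]]:
                k += 1
            avg = (i + k) / 2.0 + 1.0
            for m in range(i, k + 1):
                r[order[m]] = avg
            i = k + 1
        ranks[j] = r
    Ri = np.array([ranks[:, i].sum() for i in range(n)])
    Rbar = (n + 1) * K / 2.0
    numerator = float((Ri**2).sum() - n * Rbar**2)
    denominator = (1.0 / 12.0) * K**2 * (n**3 - n)
    return numerator / denominator


def pearson_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Cross-correlation coefficient via the explicit sum formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    num = ((x - xbar) * (y - ybar)).sum()
    den = np.sqrt(((x - xbar) ** 2).sum() * ((y - ybar) ** 2).sum())
    return float(num / den)


def pooled_two_sample_t(a: np.ndarray, b: np.ndarray) -> float:
    """Textbook pooled-variance two-sample t (b minus a)."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((b.mean() - a.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


_OFFSETS = {
    6: [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
}
_OFFSETS[18] = _OFFSETS[6] + [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if abs(dx) + abs(dy) + abs(dz) == 2
]
_OFFSETS[26] = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def flood_fill_components(binary: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D binary volume via breadth-first search.

    Returns a list of sets of (i, j, k) tuples, one per component.
    """
    binary = np.asarray(binary, dtype=bool)
    offsets = _OFFSETS[connectivity]
    seen = np.zeros_like(binary)
    components = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            p = queue.popleft()
            comp.add(p)
            for dx, dy, dz in offsets:
                q = (p[0] + dx, p[1] + dy, p[2] + dz)
                if all(0 <= qc < sc for qc, sc in zip(q, binary.shape)):
                    if binary[q] and not seen[q]:
                        seen[q] = True
                        queue.append(q)
        components.append(comp)
    return components


def fft_amplitude(x: np.ndarray, freq_hz: float, tr_seconds: float) -> float:
    """Amplitude of the component nearest freq_hz from the rFFT."""
    n = len(x)
    spec = np.abs(np.fft.rfft(x)) * 2.0 / n
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    return float(spec[np.argmin(np.abs(freqs - freq_hz))])


def explained_variance_eig(X: np.ndarray) -> np.ndarray:
    """Explained-variance ratios from an eigendecomposition of the covariance."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    vals = np.linalg.eigvalsh(cov)[::-1]
    vals = np.clip(vals, 0.0, None)
    return vals / vals.sum()


def fisher_direction_grid(X: np.ndarray, y: np.ndarray, n_angles: int = 3600) -> float:
    """Best 2D projection angle maximizing the Fisher criterion, by grid search."""
    X = np.asarray(X, dtype=float)
    X0, X1 = X[y == 0], X[y == 1]
    m0, m1 = X0.mean(axis=0), X1.mean(axis=0)
    Sw = (X0 - m0).T @ (X0 - m0) + (X1 - m1).T @ (X1 - m1)
    Sb = np.outer(m1 - m0, m1 - m0)
    best_angle, best_val = 0.0, -np.inf
    for ang in np.linspace(0.0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(ang), np.sin(ang)])
        val = (w @ Sb @ w) / (w @ Sw @ w)
        if val > best_val:
            best_angle, best_val = ang, val
    return best_angle
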