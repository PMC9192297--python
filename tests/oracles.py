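"""Independent brute-force / closed-form oracles used across tests."""

import numpy as np


def brute_force_sampen_counts(x, m, r):
    """O(N^2 m) template pair counting with plain Python loops."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std()
    tol = r * sd if sd > 0 else 1e-12
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= tol:
                b += 1
                if abs(x[i + m] - x[j + m]) <= tol:
                    a += 1
    return a, b


def geodesic_midpoint(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed form A^{1/2} (A^{-1/2} B A^{-1/2})^{1/2} A^{1/2}."""
    lam, q = np.linalg.eigh(a)
    s = (q * np.sqrt(lam)) @ q.T
    s_inv = (q / np.sqrt(lam)) @ q.T
    inner = s_inv @ b @ s_inv
    lam2, q2 = np.linalg.eigh(inner)
    return s @ ((q2 * np.sqrt(lam2)) @ q2.T) @ s


def confusion_metrics(tp, fp, tn, fn):
    """Percent accuracy/sensitivity/specificity from raw counts."""
    total = tp + fp + tn + fn
    return (100.0 * (tp + tn) / total,
            100.0 * tp / (tp + fn) if tp + fn else 100.0,
            100.0 * tn / (tn + fp) if tn + fp else 100.0)
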