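"""Independent brute-force oracles used across the test suite.

Each oracle re-derives its quantity from first principles (loops, normal
equations, exhaustive enumeration, closed forms), deliberately avoiding the
code paths of the package under test.
"""

import math

import numpy as np


def poly2_normal_equations(m: np.ndarray) -> np.ndarray:
    """Quadratic-surface coefficients by an explicit normal-equations solve."""
    n = m.shape[0]
    c = (n - 1) / 2.0
    rows = []
    b = []
    for i in range(n):
        for j in range(n):
            x, y = j - c, i - c
            rows.append([1.0, x, y, x * x, x * y, y * y])
            b.append(m[i, j])
    A = np.array(rows)
    b = np.array(b)
    return np.linalg.solve(A.T @ A, A.T @ b)


def sliding_opening(m: np.ndarray, se: int) -> np.ndarray:
    """Grayscale opening by explicit sliding min then max with edge
    replication."""
    r = se // 2
    padded = np.pad(m, r, mode="edge")
    n0, n1 = m.shape
    eroded = np.empty_like(m, dtype=float)
    for i in range(n0):
        for j in range(n1):
            eroded[i, j] = padded[i:i + se, j:j + se].min()
    padded = np.pad(eroded, r, mode="edge")
    opened = np.empty_like(m, dtype=float)
    for i in range(n0):
        for j in range(n1):
            opened[i, j] = padded[i:i + se, j:j + se].max()
    return opened


def count_glcom_pairs(q: np.ndarray, d: int, levels: int) -> np.ndarray:
    """Exhaustive directed pair count for the 45/225-degree displacement
    pair at distance d, normalized to a joint probability matrix."""
    n0, n1 = q.shape
    counts = np.zeros((levels, levels))
    for i in range(n0):
        for j in range(n1):
            # 45 degrees: d rows up, d columns right
            if i - d >= 0 and j + d < n1:
                counts[q[i, j], q[i - d, j + d]] += 1
            # 225 degrees: d rows down, d columns left
            if i + d < n0 and j - d >= 0:
                counts[q[i, j], q[i + d, j - d]] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


def u_statistic_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic over all (+,-) pairs, with half
    credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def ann_forward(w1, b1, w2, b2, x) -> float:
    """Matrix-free forward pass of the three-layer sigmoid perceptron."""

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    hidden = []
    for h in range(w1.shape[1]):
        z = b1[h]
        for i in range(w1.shape[0]):
            z += x[i] * w1[i, h]
        hidden.append(sig(z))
    z = b2
    for h, hv in enumerate(hidden):
        z += hv * w2[h]
    return sig(z)


def rank_radial_axes(ps: np.ndarray):
    """Exhaustive scorer over all quantized radial directions.

    Returns (angles_sorted_by_score, scores) where candidate angles are the
    directions from the centre to every lattice point on the boundary of
    the upper half of the grid, folded to [0, 180) degrees, each scored by
    the sum of nearest-lattice samples at radii 1 .. N/2.
    """
    N = ps.shape[0]
    h = N // 2
    cand = set()
    for a in range(-h, h + 1):
        cand.add(round(math.degrees(math.atan2(h, a)) % 180.0, 9))
    for b in range(0, h):
        cand.add(round(math.degrees(math.atan2(b, h)) % 180.0, 9))
    for b in range(1, h):
        cand.add(round(math.degrees(math.atan2(b, -h)) % 180.0, 9))
    angles = sorted(cand)
    scores = []
    for ang in angles:
        th = math.radians(ang)
        s = 0.0
        for r in range(1, h + 1):
            col = h + int(round(r * math.cos(th)))
            row = h + int(round(r * math.sin(th)))
            if not (0 <= row < N and 0 <= col < N):
                row, col = 2 * h - row, 2 * h - col
            s += ps[row, col]
        scores.append(s)
    order = sorted(range(len(angles)), key=lambda i: (-scores[i], angles[i]))
    return [angles[i] for i in order], [scores[i] for i in order]


def gaussian_blob_ps(amplitude: float, fwhm_px: float, k: int, N: int) -> float:
    """Closed-form power spectrum of a centred isotropic Gaussian blob.

    The continuous Fourier transform of A exp(-4 ln2 r^2 / F^2) is
    A pi F^2 / (4 ln2) * exp(-(pi F f)^2 / (4 ln2)) at radial frequency f
    (cycles per pixel); sampled at f = k / N and squared.
    """
    f = k / N
    sig2 = fwhm_px**2 / (8.0 * math.log(2.0))  # spatial variance
    ft = amplitude * 2.0 * math.pi * sig2 * math.exp(-2.0 * (math.pi * f) ** 2 * sig2)
    return ft**2
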