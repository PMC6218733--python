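"""Independent reference implementations used as test oracles.

Everything here is written as literal, loop-based translations of the
defining formulas, deliberately sharing no code with the package.
"""

import numpy as np

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_counts(q, levels, d, direction, mask=None):
    """Exhaustive symmetric pair enumeration for one direction."""
    h, w = q.shape
    dr, dc = (o * d for o in _OFFSETS[direction])
    counts = np.zeros((levels, levels), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if not (0 <= r2 < h and 0 <= c2 < w):
                continue
            if mask is not None and not (mask[r, c] and mask[r2, c2]):
                continue
            counts[q[r, c], q[r2, c2]] += 1
            counts[q[r2, c2], q[r, c]] += 1
    return counts


def _log(x):
    return np.log(x) if x > 0 else 0.0


def reference_features(G, central_difference_variance=False):
    """Literal term-by-term evaluation of the 16 texture statistics.

    Gray levels are 1-based.  Matches the package's documented
    definitions: |i-j| weights for dissimilarity, corrected correlation
    and variance, sum variance centered on the sum entropy, and the
    raw-moment difference variance by default.
    """
    G = np.asarray(G, dtype=float)
    N = G.shape[0]

    def g(i, j):  # 1-based accessor
        return G[i - 1, j - 1]

    mu_x = sum(j * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1))
    mu_y = sum(i * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1))
    sigma_x = (
        sum((j - mu_x) ** 2 * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1))
    ) ** 0.5
    sigma_y = (
        sum((i - mu_y) ** 2 * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1))
    ) ** 0.5

    p_sum = {k: 0.0 for k in range(2, 2 * N + 1)}
    p_diff = {k: 0.0 for k in range(0, N)}
    for i in range(1, N + 1):
        for j in range(1, N + 1):
            p_sum[i + j] += g(i, j)
            p_diff[abs(i - j)] += g(i, j)

    contrast = sum(
        p * p * sum(
            g(i, j)
            for i in range(1, N + 1)
            for j in range(1, N + 1)
            if abs(i - j) == p
        )
        for p in range(0, N)
    )
    energy = sum(g(i, j) ** 2 for i in range(1, N + 1) for j in range(1, N + 1))
    dissimilarity = sum(
        abs(i - j) * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
    )
    entropy = -sum(
        g(i, j) * _log(g(i, j)) for i in range(1, N + 1) for j in range(1, N + 1)
    )
    if sigma_x * sigma_y > 0:
        correlation = sum(
            (i - mu_x) * (j - mu_y) * g(i, j)
            for i in range(1, N + 1)
            for j in range(1, N + 1)
        ) / (sigma_x * sigma_y)
    else:
        correlation = 0.0
    homogeneity = sum(
        g(i, j) / (1 + (i - j) ** 2)
        for i in range(1, N + 1)
        for j in range(1, N + 1)
    )
    mu = (mu_x + mu_y) / 2.0
    variance = sum(
        (i - mu) ** 2 * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
    )
    difference_entropy = -sum(p_diff[k] * _log(p_diff[k]) for k in range(0, N))
    sum_average = sum(k * p_sum[k] for k in range(2, 2 * N + 1))
    cluster_shade = sum(
        (i + j - mu_x - mu_y) ** 3 * g(i, j)
        for i in range(1, N + 1)
        for j in range(1, N + 1)
    )
    cluster_prominence = sum(
        (i + j - mu_x - mu_y) ** 4 * g(i, j)
        for i in range(1, N + 1)
        for j in range(1, N + 1)
    )
    maximum_probability = max(
        g(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
    )
    if central_difference_variance:
        mu_d = sum(k * p_diff[k] for k in range(0, N))
        difference_variance = sum(
            (k - mu_d) ** 2 * p_diff[k] for k in range(0, N)
        )
    else:
        difference_variance = sum(k * k * p_diff[k] for k in range(0, N))
    autocorrelation = sum(
        i * j * g(i, j) for i in range(1, N + 1) for j in range(1, N + 1)
    )
    sum_entropy = -sum(p_sum[k] * _log(p_sum[k]) for k in range(2, 2 * N + 1))
    sum_variance = sum(
        (k - sum_entropy) ** 2 * p_sum[k] for k in range(2, 2 * N + 1)
    )

    return {
        "contrast": contrast,
        "energy": energy,
        "dissimilarity": dissimilarity,
        "entropy": entropy,
        "correlation": correlation,
        "homogeneity": homogeneity,
        "variance": variance,
        "difference_entropy": difference_entropy,
        "sum_average": sum_average,
        "cluster_shade": cluster_shade,
        "cluster_prominence": cluster_prominence,
        "maximum_probability": maximum_probability,
        "difference_variance": difference_variance,
        "autocorrelation": autocorrelation,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
    }


def random_symmetric_glcm(rng, levels):
    """A valid random GLCM: symmetric, nonnegative, sums to 1."""
    A = rng.random((levels, levels))
    A = A + A.T
    return A / A.sum()
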