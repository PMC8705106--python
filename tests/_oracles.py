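"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (explicit loops,
no shared code paths with the package) so that agreement is evidence, not
tautology.
"""

import numpy as np


def brute_force_extrema(values, N, edge_invalid=0):
    """Exhaustive evaluation of the sliding-window slope-sign predicate."""
    h = N // 2
    lo = max(h, edge_invalid)
    maxima, minima = [], []
    for i in range(lo, len(values) - lo):
        left_slopes = [(values[i] - values[j]) / (i - j) for j in range(i - h, i)]
        right_slopes = [(values[j] - values[i]) / (j - i) for j in range(i + 1, i + 1 + h)]
        if all(s > 0 for s in left_slopes) and all(s < 0 for s in right_slopes):
            maxima.append(i)
        elif all(s < 0 for s in left_slopes) and all(s > 0 for s in right_slopes):
            minima.append(i)
    return maxima, minima


def brute_force_scatter(X, labels):
    """Double-loop evaluation of the between/within scatter matrices and psi.

    X is (n, d); labels length n. Returns (sigma_inter, sigma_intra, psi)
    with the grand mean defined as the mean of class means and each class
    scatter scaled by 1/n_classes.
    """
    classes = []
    for l in labels:
        if l not in classes:
            classes.append(l)
    nc = len(classes)
    d = X.shape[1]

    mus = {}
    for c in classes:
        rows = [X[i] for i in range(len(labels)) if labels[i] == c]
        mus[c] = sum(rows) / len(rows)
    grand = sum(mus[c] for c in classes) / nc

    sigma_inter = np.zeros((d, d))
    for c in classes:
        diff = (mus[c] - grand).reshape(-1, 1)
        sigma_inter += diff @ diff.T

    sigma_intra = np.zeros((d, d))
    for c in classes:
        for i in range(len(labels)):
            if labels[i] == c:
                diff = (X[i] - mus[c]).reshape(-1, 1)
                sigma_intra += (diff @ diff.T) / nc

    psi = np.trace(sigma_inter) - np.trace(sigma_intra)
    return sigma_inter, sigma_intra, psi


def random_smooth_signal(rng, n=400, n_harmonics=4):
    """Random positive band-limited signal resembling a smoothed distance trace."""
    t = np.linspace(0.0, 1.0, n)
    y = np.zeros(n)
    for _ in range(n_harmonics):
        f = rng.uniform(1.0, 8.0)
        a = rng.uniform(0.2, 1.0)
        ph = rng.uniform(0.0, 2 * np.pi)
        y += a * np.sin(2 * np.pi * f * t + ph)
    return y - y.min() + 0.1
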