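"""Independent brute-force scalar implementations used as test oracles.

Deliberately written with explicit Python loops and no shared code with the
package's vectorised implementations.
"""

import numpy as np


def gradcam_loop(variant, A, G):
    C, H, W = A.shape
    out = np.zeros((H, W))
    if variant == "gradcam":
        for c in range(C):
            w = 0.0
            for i in range(H):
                for j in range(W):
                    w += G[c, i, j]
            w /= H * W
            for i in range(H):
                for j in range(W):
                    out[i, j] += w * A[c, i, j]
    elif variant == "gradcampp":
        for c in range(C):
            sA = 0.0
            for i in range(H):
                for j in range(W):
                    sA += A[c, i, j]
            w = 0.0
            for i in range(H):
                for j in range(W):
                    g = G[c, i, j]
                    den = 2.0 * g * g + sA * g**3
                    alpha = (g * g / den) if abs(den) > 1e-12 else 0.0
                    w += alpha * max(g, 0.0)
            for i in range(H):
                for j in range(W):
                    out[i, j] += w * A[c, i, j]
    elif variant == "hirescam":
        for c in range(C):
            for i in range(H):
                for j in range(W):
                    out[i, j] += A[c, i, j] * G[c, i, j]
    else:
        raise ValueError(variant)
    for i in range(H):
        for j in range(W):
            out[i, j] = max(out[i, j], 0.0)
    return out


def importance_loop(probs, grad):
    """Incoming-attention mass of rectified gradient-weighted attention."""
    nW, heads, N, _ = probs.shape
    w = int(round(np.sqrt(N)))
    out = np.zeros((nW, w, w))
    for win in range(nW):
        for j in range(N):
            acc = 0.0
            for h in range(heads):
                for i in range(N):
                    r = probs[win, h, i, j] * grad[win, h, i, j]
                    if r > 0:
                        acc += r
            out[win, j // w, j % w] = acc / heads
    return out


def contrast_loop(tokens, grid):
    """Inverted cosine similarity to the global mean, min-max normalised."""
    N, C = tokens.shape
    g = [sum(tokens[i][c] for i in range(N)) / N for c in range(C)]
    gn = np.sqrt(sum(v * v for v in g))
    raw = []
    for i in range(N):
        tn = np.sqrt(sum(tokens[i][c] ** 2 for c in range(C)))
        if tn < 1e-12 or gn < 1e-12:
            s = 0.0
        else:
            s = sum(tokens[i][c] * g[c] for c in range(C)) / (tn * gn)
        raw.append(1.0 - s)
    lo, hi = min(raw), max(raw)
    if hi - lo < 1e-12:
        vals = [0.0] * N
    else:
        vals = [(r - lo) / (hi - lo) for r in raw]
    return np.array(vals).reshape(grid)


def midranks(row):
    order = sorted(range(len(row)), key=lambda i: row[i])
    ranks = [0.0] * len(row)
    i = 0
    while i < len(row):
        j = i
        while j + 1 < len(row) and row[order[j + 1]] == row[order[i]]:
            j += 1
        r = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def friedman_loop(matrix):
    """Tie-corrected Friedman chi-square from first principles."""
    m = np.asarray(matrix, dtype=float)
    N, k = m.shape
    R = [0.0] * k
    ties = 0.0
    for row in m:
        rr = midranks(list(row))
        for j in range(k):
            R[j] += rr[j]
        seen = {}
        for v in row:
            seen[v] = seen.get(v, 0) + 1
        for t in seen.values():
            ties += t**3 - t
    denom = N * k * (k + 1) - ties / (k - 1)
    if denom <= 0:
        return 0.0
    num = 12.0 * sum(r * r for r in R) - 3.0 * N * N * k * (k + 1) ** 2
    return num / denom


def focal_ls_loop(logits, label, gamma, eps):
    """Scalar focal + label-smoothing loss for one sample."""
    z = np.asarray(logits, dtype=float)
    K = len(z)
    e = np.exp(z - z.max())
    p = e / e.sum()
    q = [eps / K + (1.0 - eps if k == label else 0.0) for k in range(K)]
    ce = -sum(q[k] * np.log(p[k]) for k in range(K))
    return (1.0 - p[label]) ** gamma * ce
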