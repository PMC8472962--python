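"""Independent straight-line reference computations for oracle tests.

Everything here is written with explicit per-node / per-entry Python
loops and shares no code with the package under test.  It exists so the
package's vectorised forward passes can be checked against an
implementation whose every step is obvious by inspection.
"""

import numpy as np


def neighbor_mean(A, H):
    """Weighted neighbourhood mean, self included at weight 1 (loops)."""
    n, d = H.shape
    out = np.zeros((n, d))
    for v in range(n):
        acc = H[v].astype(float).copy()
        weight = 1.0
        for u in range(n):
            acc = acc + A[v, u] * H[u]
            weight += A[v, u]
        out[v] = acc / weight
    return out


def gnn(A, H, weights, biases, inner_relu=False):
    """K mean-aggregator iterations: ReLU(mean(A, H) W + b)."""
    H = np.asarray(H, dtype=float)
    for W, b in zip(weights, biases):
        incoming = np.maximum(H, 0.0) if inner_relu else H
        H = np.maximum(neighbor_mean(A, incoming) @ W + b, 0.0)
    return H


def softmax_rows(M):
    out = np.zeros_like(M, dtype=float)
    for i in range(M.shape[0]):
        shifted = M[i] - M[i].max()
        e = np.exp(shifted)
        out[i] = e / e.sum()
    return out


def coarsen_loops(S, Z, A):
    """X' = S^T Z and A' = S^T A S by brute-force double loops."""
    n, c = S.shape
    d = Z.shape[1]
    X1 = np.zeros((c, d))
    A1 = np.zeros((c, c))
    for j in range(c):
        for k in range(d):
            X1[j, k] = sum(S[i, j] * Z[i, k] for i in range(n))
        for l in range(c):
            A1[j, l] = sum(
                S[i, j] * A[i, m] * S[m, l] for i in range(n) for m in range(n)
            )
    return X1, A1


def link_prediction(A, S):
    """Frobenius norm of A - S S^T, entry by entry."""
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            recon = sum(S[i, k] * S[j, k] for k in range(S.shape[1]))
            total += (A[i, j] - recon) ** 2
    return total**0.5


def entropy_mean(S):
    total = 0.0
    for row in S:
        h = 0.0
        for p in row:
            if p > 0:
                h -= p * np.log(p)
        total += h
    return total / S.shape[0]


def frobenius(M):
    total = 0.0
    for row in M:
        for x in row:
            total += x * x
    return total**0.5


def readout_multilevel(Zs):
    """Frobenius-normalised column means, concatenated in layer order."""
    segments = []
    for Z in Zs:
        f = frobenius(Z)
        ZF = Z / f if f > 0 else np.zeros_like(Z)
        segments.append(ZF.mean(axis=0))
    return np.concatenate(segments)


def log_softmax_row(v):
    shifted = v - v.max()
    return shifted - np.log(np.exp(shifted).sum())


def head(hG, W1, b1, W2, b2):
    hidden = np.maximum(hG @ W1 + b1, 0.0)
    return log_softmax_row(hidden @ W2 + b2)


def single_level_intermediates(A, X, p, label):
    """One FPool pooling pass end to end (K=1), every intermediate.

    Parameter dict keys: gnn.w1, gnn.b1, assign.W, assign.B,
    head.W1, head.b1, head.W2, head.b2.
    """
    Z = gnn(A, X, [p["gnn.w1"]], [p["gnn.b1"]])
    S = softmax_rows(Z @ p["assign.W"] + p["assign.B"])
    X1, A1 = coarsen_loops(S, Z, A)
    L_LP = link_prediction(A, S)
    L_E = entropy_mean(S)
    hG = readout_multilevel([Z])
    log_probs = head(hG, p["head.W1"], p["head.b1"], p["head.W2"], p["head.b2"])
    loss_classification = -log_probs[label]
    return {
        "Z": Z,
        "S": S,
        "X1": X1,
        "A1": A1,
        "L_LP": L_LP,
        "L_E": L_E,
        "hG": hG,
        "log_probs": log_probs,
        "loss_classification": loss_classification,
        "loss_total": loss_classification + L_LP + L_E,
    }


def full_fpool_forward(A, X, p, n_stages, k):
    """A complete L-stage FPool classifier with loops only.

    Parameter dict keys follow ``stage{l}.gnn.w{i}`` / ``.b{i}``,
    ``stage{l}.assign.W`` / ``.B`` and ``head.*``.
    """
    A = np.asarray(A, dtype=float)
    X = np.asarray(X, dtype=float)
    embeddings = []
    assignments = []
    for stage in range(1, n_stages + 1):
        weights = [p[f"stage{stage}.gnn.w{i}"] for i in range(1, k + 1)]
        biases = [p[f"stage{stage}.gnn.b{i}"] for i in range(1, k + 1)]
        Z = gnn(A, X, weights, biases)
        embeddings.append(Z)
        if stage < n_stages:
            S = softmax_rows(Z @ p[f"stage{stage}.assign.W"] + p[f"stage{stage}.assign.B"])
            assignments.append(S)
            X, A = coarsen_loops(S, Z, A)
    hG = readout_multilevel(embeddings)
    log_probs = head(hG, p["head.W1"], p["head.b1"], p["head.W2"], p["head.b2"])
    return {
        "embeddings": embeddings,
        "assignments": assignments,
        "hG": hG,
        "log_probs": log_probs,
    }
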