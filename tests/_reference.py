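"""Independent scalar reimplementations used as oracles in the tests.

Everything here is deliberately written with plain Python loops and no
shared code with the package, so it can serve as a hand-computation-style
cross-check of the vectorized implementation.
"""

import math


def sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def naive_forward(params, cfg, seq_matrix):
    """Scalar forward pass for ONE sequence (list of length-4 rows).

    Mirrors the architecture definition independently: valid convolution,
    ReLU, non-overlapping max pooling (remainder truncated), bidirectional
    GRU (gate order: update, reset, candidate; h = (1-z)h + z*hcand) over
    the pooled axis, concatenated final states, dense ReLU, sigmoid.
    """
    F = cfg.filter_number
    m = cfg.filter_length
    p = cfg.pool_size
    H = cfg.gru_units_per_direction
    D = cfg.dense_units
    L = len(seq_matrix)

    conv_W = params["conv_W"]
    conv = []
    for pos in range(L - m + 1):
        row = []
        for f in range(F):
            s = float(params["conv_b"][f])
            for j in range(m):
                for c in range(4):
                    s += float(conv_W[f][j][c]) * float(seq_matrix[pos + j][c])
            row.append(max(s, 0.0))
        conv.append(row)

    T = (L - m + 1) // p
    pooled = []
    for t in range(T):
        pooled.append([max(conv[t * p + k][f] for k in range(p)) for f in range(F)])

    def run_gru(inputs, W, U, b):
        h = [0.0] * H
        for x in inputs:
            z, r = [], []
            for u in range(H):
                az = float(b[u]) + sum(float(W[f][u]) * x[f] for f in range(F))
                az += sum(float(U[v][u]) * h[v] for v in range(H))
                z.append(sigmoid(az))
                ar = float(b[H + u]) + sum(float(W[f][H + u]) * x[f] for f in range(F))
                ar += sum(float(U[v][H + u]) * h[v] for v in range(H))
                r.append(sigmoid(ar))
            hc = []
            for u in range(H):
                ah = float(b[2 * H + u]) + sum(
                    float(W[f][2 * H + u]) * x[f] for f in range(F)
                )
                ah += sum(float(U[v][2 * H + u]) * (r[v] * h[v]) for v in range(H))
                hc.append(math.tanh(ah))
            h = [(1.0 - z[u]) * h[u] + z[u] * hc[u] for u in range(H)]
        return h

    h_fw = run_gru(pooled, params["gru_fw_W"], params["gru_fw_U"], params["gru_fw_b"])
    h_bw = run_gru(pooled[::-1], params["gru_bw_W"], params["gru_bw_U"],
                   params["gru_bw_b"])
    hcat = h_fw + h_bw

    dense = []
    for d in range(D):
        s = float(params["dense_b"][d])
        for v in range(2 * H):
            s += float(params["dense_W"][v][d]) * hcat[v]
        dense.append(max(s, 0.0))
    logit = float(params["out_b"]) + sum(
        float(params["out_w"][d]) * dense[d] for d in range(D)
    )
    return sigmoid(logit)


def pairwise_auc(labels, scores) -> float:
    """Brute-force Mann–Whitney AUC: enumerate all positive-negative pairs."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))
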