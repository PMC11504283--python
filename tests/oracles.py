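"""Independent brute-force oracles used by the test suite.

Every function here is a direct, scalar-level transcription of the defining
formula, written with explicit loops and kept separate from the package's
implementations so the two routes stay independent.
"""

import numpy as np


def dilated_conv_oracle(x, f, d):
    """F(t) = sum_i f(i) x(t - d i), x(tau)=0 for tau<0, by explicit loops."""
    x, f = list(x), list(f)
    out = []
    for t in range(len(x)):
        acc = 0.0
        for i in range(len(f)):
            tau = t - d * i
            if tau >= 0:
                acc += f[i] * x[tau]
        out.append(acc)
    return np.array(out)


def ratio_loss_oracle(pos_sims, neg_sims, temperature=None):
    """-log(sum_p s_p / (sum_p s_p + sum_n s_n)); softened if temperature."""
    if temperature is not None:
        pos = sum(np.exp(s / temperature) for s in pos_sims)
        neg = sum(np.exp(s / temperature) for s in neg_sims)
    else:
        pos = sum(pos_sims)
        neg = sum(neg_sims)
    return -np.log(pos / (pos + neg))


def smcl_oracle(sims, alpha):
    """1/2 sum_i (s_i - alpha)^2."""
    return 0.5 * sum((s - alpha) ** 2 for s in sims)


def softmax_oracle(row):
    """Explicit exp/normalize of one logit row."""
    e = [np.exp(v) for v in row]
    z = sum(e)
    return np.array([v / z for v in e])


def attention_oracle(q_seq, kv_seq, wq, wk, wv, wo, n_heads):
    """Multi-head attention by explicit loops over queries, keys and heads."""
    q_seq = np.asarray(q_seq)
    kv_seq = np.asarray(kv_seq)
    width = q_seq.shape[1]
    d_k = width // n_heads
    Q = q_seq @ wq
    K = kv_seq @ wk
    V = kv_seq @ wv
    head_outs = []
    for h in range(n_heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        out_h = np.zeros((q_seq.shape[0], d_k))
        for t in range(q_seq.shape[0]):
            scores = []
            for s in range(kv_seq.shape[0]):
                scores.append(float(Q[t, sl] @ K[s, sl]) / np.sqrt(d_k))
            weights = softmax_oracle(scores)
            for s in range(kv_seq.shape[0]):
                out_h[t] += weights[s] * V[s, sl]
        head_outs.append(out_h)
    return np.concatenate(head_outs, axis=1) @ wo


def periodogram_band_power(x, fs, lo, hi):
    """Band power from a direct discrete Fourier transform of the block."""
    x = np.asarray(x, dtype=float)
    n = x.size
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    # one-sided power spectrum normalized so the sum equals mean(x^2)
    p = (np.abs(X) ** 2) / n**2
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    mask = (freqs >= lo) & (freqs < hi)
    return float(p[mask].sum())


def block_starts_bruteforce(duration, block_len, hop):
    """All valid window start times by enumeration on a fine grid."""
    starts = []
    k = 0
    while True:
        t0 = k * hop
        if t0 + block_len > duration + 1e-9:
            break
        starts.append(t0)
        k += 1
    return starts


def confusion_metrics_oracle(pred, true, n_classes):
    """Per-class one-vs-rest counts, accuracy and macro F1 by explicit loops."""
    f1s = []
    for c in range(n_classes):
        tp = fp = fn = tn = 0
        for p, t in zip(pred, true):
            if p == c and t == c:
                tp += 1
            elif p == c:
                fp += 1
            elif t == c:
                fn += 1
            else:
                tn += 1
        f1s.append(2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0)
    acc = sum(1 for p, t in zip(pred, true) if p == t) / len(true)
    return acc, float(np.mean(f1s))
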