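"""Brute-force reference implementations used only by the test suite.

Each oracle recomputes a quantity by direct summation or exhaustive
enumeration, independently of the package's vectorized code paths.
"""

import numpy as np


def autocorr_brute(x):
    x = np.asarray(x, float)
    n = len(x)
    r = np.zeros(n)
    for l in range(n):
        for i in range(n - l):
            r[l] += x[i + l] * x[i]
    return r / n


def dft_power_brute(frame, fft_size):
    frame = np.asarray(frame, float)
    padded = np.zeros(fft_size)
    padded[:len(frame)] = frame
    K = fft_size // 2 + 1
    out = np.zeros(K)
    for k in range(K):
        re = im = 0.0
        for n in range(fft_size):
            ang = 2 * np.pi * k * n / fft_size
            re += padded[n] * np.cos(ang)
            im -= padded[n] * np.sin(ang)
        out[k] = re * re + im * im
    return out


def mfsc_brute(power, H, floor):
    n_frames, _ = power.shape
    n_filt = H.shape[0]
    out = np.zeros((n_frames, n_filt))
    for t in range(n_frames):
        for n in range(n_filt):
            e = 0.0
            for k in range(H.shape[1]):
                e += power[t, k] * H[n, k]
            out[t, n] = np.log(max(e, floor))
    return out


def mixed_pool_brute(x, size, lam):
    """x: (H, W) single map; replicate-pad then per-region lam*max+(1-lam)*mean."""
    x = np.asarray(x, float)
    h, w = x.shape
    ph, pw = (-h) % size, (-w) % size
    x = np.pad(x, ((0, ph), (0, pw)), mode="edge")
    ho, wo = x.shape[0] // size, x.shape[1] // size
    out = np.zeros((ho, wo))
    for i in range(ho):
        for j in range(wo):
            r = x[i * size:(i + 1) * size, j * size:(j + 1) * size]
            out[i, j] = lam * r.max() + (1 - lam) * r.mean()
    return out


def overlay_brute(M, G, mask):
    M, G = np.asarray(M, float), np.asarray(G, float)
    out = np.zeros_like(M)
    for t in range(M.shape[0]):
        for c in range(M.shape[1]):
            s = M[t, c] + G[t, c]
            out[t, c] = s if mask[t] else s / 2.0
    return out


def depthwise_separable_brute(x, dw, pw, b):
    """x: (C, H, W); dw: (C, k, k); pw: (O, C); b: (O,) -> (O, H, W).

    Same-padded cross-correlation per channel, then a 1x1 channel mix.
    """
    c, h, w = x.shape
    k = dw.shape[1]
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p)))
    mid = np.zeros((c, h, w))
    for ch in range(c):
        for i in range(h):
            for j in range(w):
                acc = 0.0
                for u in range(k):
                    for v in range(k):
                        acc += dw[ch, u, v] * xp[ch, i + u, j + v]
                mid[ch, i, j] = acc
    o = pw.shape[0]
    out = np.zeros((o, h, w))
    for oo in range(o):
        out[oo] = b[oo]
        for ch in range(c):
            out[oo] += pw[oo, ch] * mid[ch]
    return out


# ---------------------------------------------------------------------------
# duration-explicit Viterbi by exhaustive enumeration

def _compositions(total, parts):
    if total == 0:
        yield ()
        return
    for p in parts:
        if p <= total:
            for rest in _compositions(total - p, parts):
                yield (p,) + rest


def viterbi_brute(obs, model):
    """Best (score, per-frame states) over all admissible segmentations."""
    t_total = len(obs)
    log_pi = np.log(model.pi)
    log_b = np.empty((4, t_total))
    for j in range(4):
        v = model.emission_var[j]
        log_b[j] = -0.5 * (np.log(2 * np.pi * v) + (obs - model.emission_mean[j]) ** 2 / v)
    pmfs = {}
    for j in range(4):
        ds, lp = model.duration_log_pmf(j)
        pmfs[j] = dict(zip(ds.tolist(), lp.tolist()))
    parts = sorted(set(d for j in range(4) for d in pmfs[j]))

    best_score, best_states = -np.inf, None
    for first_state in range(4):
        for comp in _compositions(t_total, parts):
            score, states, t = 0.0, [], 0
            ok = True
            for seg_i, d in enumerate(comp):
                j = (first_state + seg_i) % 4
                if d not in pmfs[j]:
                    ok = False
                    break
                score += pmfs[j][d] + log_b[j, t:t + d].sum()
                states.extend([j] * d)
                t += d
            if not ok:
                continue
            score += log_pi[first_state]
            if score > best_score:
                best_score, best_states = score, np.asarray(states, dtype=np.int8)
    return best_score, best_states
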