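"""Independent brute-force oracles used to cross-check the implementations.

Each oracle deliberately avoids the code path it checks: plain Python
loops, exhaustive candidate enumeration, dense grid searches.
"""

import numpy as np


def circular_signed_diff_oracle(a, b, period=24.0):
    """Smallest signed difference a-b by enumerating +/- period candidates;
    ties at half a cycle resolve to the positive branch."""
    best = None
    for k in (-2, -1, 0, 1, 2):
        cand = a - b + k * period
        if best is None or abs(cand) < abs(best) - 1e-12 or (
            abs(abs(cand) - abs(best)) <= 1e-12 and cand > best
        ):
            best = cand
    return best


def circular_mean_oracle(hours, period=24.0):
    ang = np.asarray(hours) * 2 * np.pi / period
    m = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return m * period / (2 * np.pi) % period


def step_template_onsets_oracle(counts, bin_minutes, n_days, window_h=6.0,
                                anchor_zt=4.0):
    """Exhaustive per-day argmax of the 6h/6h mean-difference template,
    scanning every bin boundary with explicit loops."""
    counts = np.asarray(counts, dtype=float)
    w = int(round(window_h * 60 / bin_minutes))
    bpd = 1440 // bin_minutes
    anchor = int(round(anchor_zt * 60 / bin_minutes))
    n = counts.size
    onsets = []
    for d in range(n_days):
        t0 = d * bpd + anchor
        best_s, best_t = -np.inf, None
        for t in range(max(1, t0), min(n, t0 + bpd)):
            left = counts[max(0, t - w):t]
            right = counts[t:min(n, t + w)]
            if left.size == 0 or right.size == 0:
                continue
            s = right.mean() - left.mean()
            if s > best_s:
                best_s, best_t = s, t
        onsets.append((best_t * bin_minutes % 1440) / 60.0)
    return np.array(onsets)


def q_stat_oracle(counts, period_bins):
    """Sokolove-Bushell Q for one candidate period via explicit double loop."""
    x = np.asarray(counts, dtype=float)
    k = x.size // period_bins
    used = x[: k * period_bins]
    n = used.size
    mbar = sum(used) / n
    col_means = []
    for h in range(period_bins):
        acc = 0.0
        for c in range(k):
            acc += used[c * period_bins + h]
        col_means.append(acc / k)
    num = sum((m - mbar) ** 2 for m in col_means)
    den = sum((v - mbar) ** 2 for v in used)
    return k * n * num / den


def cosinor_acrophase_grid_oracle(t, y, period=24.0, step=0.001):
    """Acrophase by dense grid search: for each candidate peak time fit
    mesor and (sign-free) amplitude by least squares, keep the SSE minimum."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    omega = 2 * np.pi / period
    acros = np.arange(0.0, period, step)
    c = np.cos(omega * (t[None, :] - acros[:, None]))  # (n_acro, n_t)
    c_mean = c.mean(axis=1, keepdims=True)
    cc = c - c_mean
    yc = y - y.mean()
    denom = np.sum(cc * cc, axis=1)
    amp = np.where(denom > 0, (cc @ yc) / np.maximum(denom, 1e-300), 0.0)
    resid = yc[None, :] - amp[:, None] * cc
    sse = np.sum(resid**2, axis=1)
    # negative fitted amplitude means the true peak is half a cycle away
    best = int(np.argmin(sse))
    acro = acros[best]
    if amp[best] < 0:
        acro = (acro + period / 2) % period
    return acro


def permutation_two_sample_oracle(a, b, n_perm=2000, rng=None):
    """Two-sided permutation p-value for a difference in means."""
    rng = rng or np.random.default_rng(0)
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[: a.size].mean() - perm[a.size:].mean())
        if d >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
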