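"""Independent brute-force reference implementations used only by tests.

Each function is written directly from the statistical definition with
plain Python loops, deliberately sharing no code with the package.
"""

import itertools
import math


def oracle_signal_features(values):
    """The 28 signal-distribution features, computed naively."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mu = sum(v) / n
    var = sum((x - mu) ** 2 for x in v) / n
    sd = math.sqrt(var)

    def percentile(level):
        # linear interpolation between order statistics (numpy 'linear')
        h = (n - 1) * level / 100.0
        lo = math.floor(h)
        hi = math.ceil(h)
        return v[lo] + (h - lo) * (v[hi] - v[lo])

    levels = [0.01, 1, 5, 25, 50, 75, 95, 99, 99.99]
    p = {lv: percentile(lv) for lv in levels}

    core = [x for x in v if p[5] <= x <= p[95]]
    mu_c = sum(core) / len(core)
    sd_c = math.sqrt(sum((x - mu_c) ** 2 for x in core) / len(core))

    if sd == 0:
        entropy, energy, skew, kurt = 0.0, 1.0, 0.0, 0.0
    else:
        nbins = 64
        lo, hi = v[0], v[-1]
        width = (hi - lo) / nbins
        counts = [0] * nbins
        for x in v:
            b = min(int((x - lo) / width), nbins - 1)
            counts[b] += 1
        probs = [c / n for c in counts if c > 0]
        entropy = -sum(q * math.log2(q) for q in probs)
        energy = sum(q * q for q in probs)
        skew = (sum((x - mu) ** 3 for x in v) / n) / sd**3
        kurt = (sum((x - mu) ** 4 for x in v) / n) / sd**4 - 3.0

    med = percentile(50)
    abs_dev = sorted(abs(x - med) for x in v)
    h = (n - 1) * 0.5
    lo_i = math.floor(h)
    mad = abs_dev[lo_i] + (h - lo_i) * (abs_dev[math.ceil(h)] - abs_dev[lo_i])

    out = {
        "mean": mu,
        "sd": sd,
        "icv": sd / mu,
        "skewness": skew,
        "kurtosis": kurt,
        "entropy": entropy,
        "energy": energy,
        "mean_c90": mu_c,
        "sd_c90": sd_c,
        "icv_c90": sd_c / mu_c,
        "precision_range": p[95] - p[5],
        "min": v[0],
        "max": v[-1],
        "range": v[-1] - v[0],
        "mad": mad,
        "p_below_2sd": sum(1 for x in v if x < mu - 2 * sd) / n if sd else 0.0,
        "p_below_3sd": sum(1 for x in v if x < mu - 3 * sd) / n if sd else 0.0,
        "p_above_2sd": sum(1 for x in v if x > mu + 2 * sd) / n if sd else 0.0,
        "p_above_3sd": sum(1 for x in v if x > mu + 3 * sd) / n if sd else 0.0,
    }
    for lv in levels:
        out[f"value_at_{lv:g}"] = p[lv]
    return out


def oracle_mass_scatter(indices, values, spacing):
    """Intensity-weighted second central moment tensor by double loop."""
    pts = [[i * s for i, s in zip(ix, spacing)] for ix in indices]
    wsum = sum(values)
    c = [sum(w * p[a] for w, p in zip(values, pts)) / wsum for a in range(3)]
    m = [[0.0] * 3 for _ in range(3)]
    for w, p in zip(values, pts):
        for a in range(3):
            for b in range(3):
                m[a][b] += w * (p[a] - c[a]) * (p[b] - c[b])
    return [[m[a][b] / wsum for b in range(3)] for a in range(3)]


def oracle_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    n1 = len(x)
    w_obs = sum(ranks[v] for v in x)
    mean_w = n1 * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - mean_w)
    total = extreme = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(combo) - mean_w) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def oracle_bh(p_values):
    """Benjamini-Hochberg step-up q-values by direct definition."""
    m = len(p_values)
    indexed = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = indexed[rank_from_top - 1]
        val = min(prev, p_values[i] * m / rank_from_top)
        q[i] = min(val, 1.0)
        prev = val
    return q
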