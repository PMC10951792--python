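"""Auto-threshold methods against independently coded reference definitions.

Each reference below is written directly from the published definition of
the method (brute-force/exhaustive-search formulations where the method is
defined by optimizing a criterion), independent of the package's own code
paths, and the two are required to agree exactly.
"""

from __future__ import annotations

import numpy as np
import pytest

from celltyper.thresholds import THRESHOLD_METHODS, auto_threshold

from conftest import bimodal_histogram


# ---------------------------------------------------------------------------
# reference implementations (oracles)


def _occupied(h):
    nz = np.nonzero(h)[0]
    return int(nz[0]), int(nz[-1])


def ref_otsu(h):
    # exhaustive search maximizing between-class variance
    total = h.sum()
    best_t, best = 0, -1.0
    for t in range(256):
        w0 = h[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (np.arange(t + 1) * h[: t + 1]).sum() / w0
        mu1 = (np.arange(t + 1, 256) * h[t + 1 :]).sum() / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best:
            best, best_t = bcv, t
    return best_t


def ref_mean(h):
    return int(np.average(np.arange(256), weights=h))


def ref_percentile(h):
    cum = np.cumsum(h) / h.sum()
    return int(np.argmin(np.abs(cum - 0.5)))


def ref_max_entropy(h):
    p = h / h.sum()
    best_t, best = 0, -np.inf
    for t in range(255):
        pb, po = p[: t + 1].sum(), p[t + 1 :].sum()
        if pb <= 0 or po <= 0:
            continue
        hb = -sum(q / pb * np.log(q / pb) for q in p[: t + 1] if q > 0)
        ho = -sum(q / po * np.log(q / po) for q in p[t + 1 :] if q > 0)
        if hb + ho > best:
            best, best_t = hb + ho, t
    return best_t


def ref_yen(h):
    p = h / h.sum()
    best_t, best = 0, -np.inf
    for t in range(256):
        p1 = p[: t + 1].sum()
        s1 = (p[: t + 1] ** 2).sum()
        s2 = (p[t + 1 :] ** 2).sum()
        crit = -(np.log(s1 * s2) if s1 * s2 > 0 else 0.0) + 2 * (
            np.log(p1 * (1 - p1)) if 0 < p1 < 1 else 0.0
        )
        if crit > best:
            best, best_t = crit, t
    return best_t


def ref_shanbhag(h):
    p = h / h.sum()
    P1 = np.cumsum(p)
    P2 = 1 - P1
    first, last = _occupied(h)
    best_t, best = first, np.inf
    for t in range(first, last + 1):
        if P1[t] <= 0 or P2[t] <= 0:
            continue
        term = 0.5 / P1[t]
        eb = -sum(
            p[i] * np.log(1 - term * P1[i - 1])
            for i in range(1, t + 1)
            if 1 - term * P1[i - 1] > 0
        ) * term
        term = 0.5 / P2[t]
        eo = -sum(
            p[i] * np.log(1 - term * P2[i])
            for i in range(t + 1, 256)
            if 1 - term * P2[i] > 0
        ) * term
        if abs(eb - eo) < best:
            best, best_t = abs(eb - eo), t
    return best_t


def ref_huang(h):
    first, last = _occupied(h)
    C = last - first
    W = np.cumsum(np.arange(256) * h)
    S = np.cumsum(h)

    def fuzzy_entropy(t):
        ent = 0.0
        mu_b = int(round(W[t] / S[t]))
        for i in range(first, t + 1):
            mu = 1.0 / (1.0 + abs(i - mu_b) / C)
            if 0 < mu < 1:
                ent += (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu)) * h[i]
        if S[last] > S[t]:
            mu_o = int(round((W[last] - W[t]) / (S[last] - S[t])))
            for i in range(t + 1, last + 1):
                mu = 1.0 / (1.0 + abs(i - mu_o) / C)
                if 0 < mu < 1:
                    ent += (-mu * np.log(mu) - (1 - mu) * np.log(1 - mu)) * h[i]
        return ent

    ents = [fuzzy_entropy(t) for t in range(first, last + 1)]
    return first + int(np.argmin(ents))


def ref_moments(h):
    p = h / h.sum()
    i = np.arange(256.0)
    m1, m2, m3 = (i * p).sum(), (i**2 * p).sum(), (i**3 * p).sum()
    cd = m2 - m1 * m1
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    z0, z1 = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    return int(np.argmax(cum > p0))


def ref_triangle(h):
    data = h.astype(float).copy()
    nz = np.nonzero(data)[0]
    lo = max(nz[0] - 1, 0)
    hi = min(nz[-1] + 1, 255)
    peak = int(np.argmax(data))
    inverted = (peak - lo) < (hi - peak)
    if inverted:
        data = data[::-1].copy()
        lo, peak = 255 - hi, 255 - peak
    if lo == peak:
        return lo
    # distance from the chord joining (lo, h[lo]) to (peak, h[peak])
    nx, ny = data[peak], lo - peak
    norm = np.hypot(nx, ny)
    nx, ny = nx / norm, ny / norm
    d0 = nx * lo + ny * data[lo]
    dist = [nx * i + ny * data[i] - d0 for i in range(lo + 1, peak + 1)]
    split = lo + 1 + int(np.argmax(dist)) - 1
    return 255 - split if inverted else split


def ref_isodata(h):
    i = np.arange(256)
    g = int(np.nonzero(h)[0][0]) + 1
    while g <= 254:
        wl, wh = h[:g].sum(), h[g + 1 :].sum()
        if wl > 0 and wh > 0:
            ml = (i[:g] * h[:g]).sum() / wl
            mh = (i[g + 1 :] * h[g + 1 :]).sum() / wh
            if g == int(round((ml + mh) / 2)):
                return g
        g += 1
    raise AssertionError("no isodata fixed point")


def ref_default(h):
    lo, hi = _occupied(h)
    i = np.arange(256)
    moving = lo
    while True:
        s2 = h[lo : moving + 1].sum()
        s4 = h[moving + 1 : hi + 1].sum()
        m_lo = (i[lo : moving + 1] * h[lo : moving + 1]).sum() / s2
        m_hi = (i[moving + 1 : hi + 1] * h[moving + 1 : hi + 1]).sum() / s4
        result = (m_lo + m_hi) / 2
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            return int(round(result))


def ref_li(h):
    i = np.arange(256.0)
    n = h.sum()
    new_t = (i * h).sum() / n
    old_t = np.inf
    t = 0
    while abs(new_t - old_t) > 0.5:
        old_t = new_t
        t = int(old_t + 0.5)
        nb, no = h[: t + 1].sum(), h[t + 1 :].sum()
        mb = (i[: t + 1] * h[: t + 1]).sum() / nb if nb else 0.0
        mo = (i[t + 1 :] * h[t + 1 :]).sum() / no if no else 0.0
        if mb <= 0 or mo <= 0 or mb == mo:
            break
        val = (mb - mo) / (np.log(mb) - np.log(mo))
        new_t = int(val - 0.5) if val < 0 else int(val + 0.5)
    return t


def ref_min_error(h):
    i = np.arange(256.0)
    A = np.cumsum(h)
    B = np.cumsum(i * h)
    C = np.cumsum(i**2 * h)
    t = ref_mean(h)
    prev = -2
    while t != prev:
        if A[t] <= 0 or A[255] - A[t] <= 0:
            break
        mu, nu = B[t] / A[t], (B[255] - B[t]) / (A[255] - A[t])
        p, q = A[t] / A[255], (A[255] - A[t]) / A[255]
        s2 = C[t] / A[t] - mu**2
        tau2 = (C[255] - C[t]) / (A[255] - A[t]) - nu**2
        if s2 <= 0 or tau2 <= 0:
            break
        w0 = 1 / s2 - 1 / tau2
        w1 = mu / s2 - nu / tau2
        w2 = mu**2 / s2 - nu**2 / tau2 + np.log10((s2 * q * q) / (tau2 * p * p))
        sq = w1 * w1 - w0 * w2
        if sq < 0:
            break
        prev = t
        with np.errstate(divide="ignore", invalid="ignore"):
            temp = (w1 + np.sqrt(sq)) / w0
        if np.isnan(temp) or np.isinf(temp):
            t = prev
        else:
            t = min(max(int(temp + 0.5), 0), 255)
    return t


def _smooth_bimodal(h):
    y = h.astype(float).copy()
    def modes(y):
        return sum(
            1 for k in range(1, 255) if y[k - 1] < y[k] and y[k + 1] < y[k]
        )
    it = 0
    while modes(y) != 2:
        t = np.empty_like(y)
        t[0] = (y[0] + y[1]) / 3
        t[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3
        t[-1] = (y[-2] + y[-1]) / 3
        y = t
        it += 1
        assert it < 10000
    return y


def ref_intermodes(h):
    y = _smooth_bimodal(h)
    peaks = [k for k in range(1, 255) if y[k - 1] < y[k] and y[k + 1] < y[k]]
    return int(round(sum(peaks) / 2))


def ref_minimum(h):
    y = _smooth_bimodal(h)
    for k in range(1, 255):
        if y[k - 1] > y[k] and y[k + 1] >= y[k]:
            return k
    raise AssertionError


def ref_renyi(h):
    p = h / h.sum()
    P1 = np.cumsum(p)
    first, last = _occupied(h)

    def argbest(order):
        best_t, best = first, -np.inf
        for t in range(first, last + 1):
            pb, po = P1[t], 1 - P1[t]
            if pb <= 0 or po <= 0:
                continue
            if order == 1:
                v = -sum(q / pb * np.log(q / pb) for q in p[: t + 1] if q > 0) - sum(
                    q / po * np.log(q / po) for q in p[t + 1 :] if q > 0
                )
            elif order == 0.5:
                prod = np.sqrt(p[: t + 1] / pb).sum() * np.sqrt(p[t + 1 :] / po).sum()
                v = np.log(prod) if prod > 0 else 0.0
            else:
                prod = ((p[: t + 1] / pb) ** 2).sum() * ((p[t + 1 :] / po) ** 2).sum()
                v = -np.log(prod) if prod > 0 else 0.0
            if v > best:
                best, best_t = v, t
        return best_t

    t1, t2, t3 = sorted([argbest(0.5), argbest(1), argbest(2)])
    if abs(t1 - t2) <= 5:
        b = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        b = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    w = P1[t3] - P1[t1]
    return int(
        t1 * (P1[t1] + 0.25 * w * b[0])
        + 0.25 * t2 * w * b[1]
        + t3 * (1 - P1[t3] + 0.25 * w * b[2])
    )


REFERENCES = {
    "Default": ref_default,
    "Huang": ref_huang,
    "Intermodes": ref_intermodes,
    "IsoData": ref_isodata,
    "Li": ref_li,
    "MaxEntropy": ref_max_entropy,
    "Mean": ref_mean,
    "MinError(I)": ref_min_error,
    "Minimum": ref_minimum,
    "Moments": ref_moments,
    "Otsu": ref_otsu,
    "Percentile": ref_percentile,
    "RenyiEntropy": ref_renyi,
    "Shanbhag": ref_shanbhag,
    "Triangle": ref_triangle,
    "Yen": ref_yen,
}


# ---------------------------------------------------------------------------
# tests


def test_all_sixteen_methods_present():
    assert set(THRESHOLD_METHODS) == set(REFERENCES)
    assert len(THRESHOLD_METHODS) == 16


@pytest.mark.parametrize("method", sorted(REFERENCES))
def test_oracle_equivalence_on_random_histograms(method):
    """Each method matches its reference definition on 50 random histograms."""
    rng = np.random.default_rng(1234)
    for _ in range(50):
        h = bimodal_histogram(rng)
        assert auto_threshold(h, method) == REFERENCES[method](h), method


def test_otsu_two_spike_histogram_matches_brute_force():
    h = np.zeros(256)
    h[10], h[200] = 100, 100
    t = auto_threshold(h, "Otsu")
    assert t == ref_otsu(h)
    assert 10 <= t < 200  # separates the two spikes


def test_mean_of_flat_histogram_is_127():
    h = np.ones(256)
    assert auto_threshold(h, "Mean") == 127


def test_constant_image_histogram_rejected():
    h = np.zeros(256)
    h[42] = 1000
    with pytest.raises(ValueError, match="no threshold separates"):
        auto_threshold(h, "Otsu")


def test_unknown_method_lists_valid_names():
    with pytest.raises(ValueError, match="Otsu"):
        auto_threshold(np.ones(256), "NotAMethod")


def test_skimage_cross_check_on_shared_formulations():
    """Methods whose published definition skimage also implements agree
    closely with it (an independent third implementation)."""
    from skimage.filters import threshold_isodata, threshold_mean, threshold_otsu, threshold_yen

    rng = np.random.default_rng(7)
    bins = np.arange(256)
    for _ in range(10):
        h = bimodal_histogram(rng)
        assert auto_threshold(h, "Otsu") == int(threshold_otsu(hist=(h, bins)))
        assert auto_threshold(h, "Yen") == int(threshold_yen(hist=(h, bins)))
        assert abs(auto_threshold(h, "Mean") - threshold_mean(np.repeat(bins, h))) <= 1
        assert abs(auto_threshold(h, "IsoData") - int(threshold_isodata(hist=(h, bins)))) <= 1
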