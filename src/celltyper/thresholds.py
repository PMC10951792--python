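"""Global auto-threshold methods over 256-bin histograms.

Sixteen classical histogram-shape / clustering / entropy methods are
provided: Default, Huang, Intermodes, IsoData, Li, MaxEntropy, Mean,
MinError(I), Minimum, Moments, Otsu, Percentile, RenyiEntropy, Shanbhag,
Triangle, and Yen. Each takes a 256-bin count histogram and returns an
integer level ``t`` in 0..255 with the convention that pixels strictly
greater than ``t`` are foreground (bright objects on a dark background).

"Default" is the legacy isodata variant (iterative intermeans with the
moving-index stopping rule) that differs slightly from the plain
Ridler–Calvard "IsoData" iteration; both are provided since they can
disagree by a level on skewed histograms.

References: Ridler & Calvard 1978 (isodata); Huang & Wang 1995; Prewitt &
Mendelsohn 1966 (intermodes/minimum); Li & Tam 1998; Kapur, Sahoo & Wong
1985 (max-entropy); Glasbey 1993 (mean); Kittler & Illingworth 1986
(min-error); Tsai 1985 (moments); Otsu 1979; Doyle 1962 (percentile);
Sahoo et al. 1997 (Renyi); Shanbhag 1994; Zack et al. 1977 (triangle);
Yen, Chang & Chang 1995.
"""

from __future__ import annotations

import numpy as np

__all__ = ["THRESHOLD_METHODS", "auto_threshold"]


def _validate(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have exactly 256 bins")
    if hist.sum() <= 0:
        raise ValueError("histogram is empty")
    if np.count_nonzero(hist) < 2:
        raise ValueError("no threshold separates foreground: constant image")
    return hist


def _occupied_range(hist: np.ndarray) -> tuple[int, int]:
    nz = np.nonzero(hist)[0]
    return int(nz[0]), int(nz[-1])


# ---------------------------------------------------------------------------
# individual methods


def _default(hist: np.ndarray) -> int:
    # legacy isodata variant: intermeans with a moving lower partition index
    lo, hi = _occupied_range(hist)
    if lo >= hi:
        return len(hist) // 2
    moving = lo
    while True:
        sum1 = sum2 = sum3 = sum4 = 0.0
        for i in range(lo, moving + 1):
            sum1 += i * hist[i]
            sum2 += hist[i]
        for i in range(moving + 1, hi + 1):
            sum3 += i * hist[i]
            sum4 += hist[i]
        result = (sum1 / sum2 + sum3 / sum4) / 2.0 if sum2 > 0 and sum4 > 0 else moving
        moving += 1
        if not (moving + 1 <= result and moving < hi - 1):
            break
    return int(round(result))


def _isodata(hist: np.ndarray) -> int:
    # Ridler–Calvard: t = mean of the two class means, iterated from below
    g = 0
    for i in range(1, 256):
        if hist[i] > 0:
            g = i + 1
            break
    while True:
        totl = hist[:g].sum()
        l = (np.arange(g) * hist[:g]).sum()
        toth = hist[g + 1 :].sum()
        h = (np.arange(g + 1, 256) * hist[g + 1 :]).sum()
        if totl > 0 and toth > 0:
            l /= totl
            h /= toth
            if g == int(round((l + h) / 2.0)):
                break
        g += 1
        if g > 254:
            raise ValueError("isodata iteration did not converge")
    return g


def _huang(hist: np.ndarray) -> int:
    # minimize fuzziness measured by Shannon entropy of the membership function
    first, last = _occupied_range(hist)
    S = np.zeros(last + 1)
    W = np.zeros(last + 1)
    S[0] = hist[0]
    for i in range(max(1, first), last + 1):
        S[i] = S[i - 1] + hist[i]
        W[i] = W[i - 1] + i * hist[i]
    C = float(last - first)
    Smu = np.zeros(last + 1 - first)
    for i in range(1, len(Smu)):
        mu = 1.0 / (1.0 + i / C)
        Smu[i] = -mu * np.log(mu) - (1.0 - mu) * np.log(1.0 - mu)
    best, best_ent = first, np.inf
    for t in range(first, last + 1):
        ent = 0.0
        mu = int(round(W[t] / S[t]))
        for i in range(first, t + 1):
            ent += Smu[abs(i - mu)] * hist[i]
        if S[last] - S[t] > 0:
            mu2 = int(round((W[last] - W[t]) / (S[last] - S[t])))
            for i in range(t + 1, last + 1):
                ent += Smu[abs(i - mu2)] * hist[i]
        if ent < best_ent:
            best_ent, best = ent, t
    return best


def _bimodal_test(y: np.ndarray) -> bool:
    modes = 0
    for k in range(1, len(y) - 1):
        if y[k - 1] < y[k] and y[k + 1] < y[k]:
            modes += 1
            if modes > 2:
                return False
    return modes == 2


def _smooth_until_bimodal(hist: np.ndarray) -> np.ndarray:
    y = hist.astype(np.float64).copy()
    it = 0
    while not _bimodal_test(y):
        t = np.empty_like(y)
        t[0] = (y[0] + y[1]) / 3.0
        t[1:-1] = (y[:-2] + y[1:-1] + y[2:]) / 3.0
        t[-1] = (y[-2] + y[-1]) / 3.0
        y = t
        it += 1
        if it > 10000:
            raise ValueError("histogram could not be smoothed to bimodality")
    return y


def _intermodes(hist: np.ndarray) -> int:
    y = _smooth_until_bimodal(hist)
    peaks = [k for k in range(1, 255) if y[k - 1] < y[k] and y[k + 1] < y[k]]
    return int(round(sum(peaks) / 2.0))


def _minimum(hist: np.ndarray) -> int:
    y = _smooth_until_bimodal(hist)
    for i in range(1, 255):
        if y[i - 1] > y[i] and y[i + 1] >= y[i]:
            return i
    raise ValueError("no minimum between modes found")


def _li(hist: np.ndarray) -> int:
    # iterative minimum cross-entropy
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    mean = (levels * hist).sum() / n
    new_t = mean
    old_t = -np.inf
    threshold = 0
    while abs(new_t - old_t) > 0.5:
        old_t = new_t
        threshold = int(old_t + 0.5)
        num_back = hist[: threshold + 1].sum()
        sum_back = (levels[: threshold + 1] * hist[: threshold + 1]).sum()
        mean_back = sum_back / num_back if num_back > 0 else 0.0
        num_obj = hist[threshold + 1 :].sum()
        sum_obj = (levels[threshold + 1 :] * hist[threshold + 1 :]).sum()
        mean_obj = sum_obj / num_obj if num_obj > 0 else 0.0
        if mean_back <= 0 or mean_obj <= 0 or mean_back == mean_obj:
            break
        temp = (mean_back - mean_obj) / (np.log(mean_back) - np.log(mean_obj))
        new_t = int(temp - 0.5) if temp < -2.22e-16 else int(temp + 0.5)
    return threshold


def _max_entropy(hist: np.ndarray) -> int:
    # Kapur–Sahoo–Wong: maximize summed background+object Shannon entropy
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    first, last = _occupied_range(hist)
    best, best_ent = first, -np.inf
    for t in range(first, last + 1):
        P2t = 1.0 - P1[t]
        if P1[t] <= 0 or P2t <= 0:
            continue
        pb = p[: t + 1]
        pb = pb[pb > 0] / P1[t]
        ent_back = -(pb * np.log(pb)).sum()
        po = p[t + 1 :]
        po = po[po > 0] / P2t
        ent_obj = -(po * np.log(po)).sum()
        tot = ent_back + ent_obj
        if tot > best_ent:
            best_ent, best = tot, t
    return best


def _mean(hist: np.ndarray) -> int:
    levels = np.arange(256, dtype=np.float64)
    return int((levels * hist).sum() / hist.sum())


def _min_error(hist: np.ndarray) -> int:
    # Kittler–Illingworth iterative minimum-error, seeded at the mean
    def A(j):
        return hist[: j + 1].sum()

    def B(j):
        return (np.arange(j + 1) * hist[: j + 1]).sum()

    def C(j):
        return (np.arange(j + 1, dtype=np.float64) ** 2 * hist[: j + 1]).sum()

    threshold = _mean(hist)
    t_prev = -2
    total_a, total_b, total_c = A(255), B(255), C(255)
    while threshold != t_prev:
        at = A(threshold)
        if at <= 0 or total_a - at <= 0:
            break
        mu = B(threshold) / at
        nu = (total_b - B(threshold)) / (total_a - at)
        p = at / total_a
        q = (total_a - at) / total_a
        sigma2 = C(threshold) / at - mu * mu
        tau2 = (total_c - C(threshold)) / (total_a - at) - nu * nu
        if sigma2 <= 0 or tau2 <= 0:
            break
        w0 = 1.0 / sigma2 - 1.0 / tau2
        w1 = mu / sigma2 - nu / tau2
        w2 = mu * mu / sigma2 - nu * nu / tau2 + np.log10(
            (sigma2 * q * q) / (tau2 * p * p)
        )
        sqterm = w1 * w1 - w0 * w2
        if sqterm < 0:
            break
        t_prev = threshold
        with np.errstate(divide="ignore", invalid="ignore"):
            temp = (w1 + np.sqrt(sqterm)) / w0
        if np.isnan(temp) or np.isinf(temp):
            threshold = t_prev
        else:
            threshold = int(temp + 0.5)
            threshold = min(max(threshold, 0), 255)
    return threshold


def _moments(hist: np.ndarray) -> int:
    # Tsai moment-preserving: pick the p0-tile of a two-level image with
    # identical first three moments
    total = hist.sum()
    p = hist / total
    levels = np.arange(256, dtype=np.float64)
    m1 = (levels * p).sum()
    m2 = (levels**2 * p).sum()
    m3 = (levels**3 * p).sum()
    cd = m2 - m1 * m1
    if cd == 0:
        raise ValueError("degenerate histogram for moment preservation")
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (-m3 + m2 * m1) / cd
    disc = c1 * c1 - 4.0 * c0
    if disc < 0:
        disc = 0.0
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate histogram for moment preservation")
    p0 = (z1 - m1) / (z1 - z0)
    s = 0.0
    for i in range(256):
        s += p[i]
        if s > p0:
            return i
    return 255


def _otsu(hist: np.ndarray) -> int:
    # maximize between-class variance; first maximizer wins
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    best, best_bcv = 0, -1.0
    sum_all = (levels * hist).sum()
    w0 = 0.0
    sum0 = 0.0
    for t in range(256):
        w0 += hist[t]
        sum0 += t * hist[t]
        w1 = total - w0
        if w0 <= 0 or w1 <= 0:
            continue
        mu0 = sum0 / w0
        mu1 = (sum_all - sum0) / w1
        bcv = w0 * w1 * (mu0 - mu1) ** 2
        if bcv > best_bcv:
            best_bcv, best = bcv, t
    return best


def _percentile(hist: np.ndarray, ptile: float = 0.5) -> int:
    frac = np.cumsum(hist) / hist.sum()
    best, best_d = 0, np.inf
    for i in range(256):
        d = abs(frac[i] - ptile)
        if d < best_d:
            best_d, best = d, i
    return best


def _renyi_partial(p: np.ndarray, P1: np.ndarray, first: int, last: int, order: float) -> int:
    best, best_ent = first, -np.inf
    for t in range(first, last + 1):
        P2t = 1.0 - P1[t]
        if P1[t] <= 0 or P2t <= 0:
            continue
        if order == 1.0:
            pb = p[: t + 1]
            pb = pb[pb > 0] / P1[t]
            ent_back = -(pb * np.log(pb)).sum()
            po = p[t + 1 :]
            po = po[po > 0] / P2t
            tot = ent_back - (po * np.log(po)).sum()
        elif order == 0.5:
            ent_back = np.sqrt(p[: t + 1] / P1[t]).sum()
            ent_obj = np.sqrt(p[t + 1 :] / P2t).sum()
            tot = np.log(ent_back * ent_obj) if ent_back * ent_obj > 0 else 0.0
        else:  # order == 2
            ent_back = ((p[: t + 1] / P1[t]) ** 2).sum()
            ent_obj = ((p[t + 1 :] / P2t) ** 2).sum()
            tot = -np.log(ent_back * ent_obj) if ent_back * ent_obj > 0 else 0.0
        if tot > best_ent:
            best_ent, best = tot, t
    return best


def _renyi_entropy(hist: np.ndarray) -> int:
    # Sahoo et al.: combine the optimal thresholds at Renyi orders 1/2, 1, 2
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    first, last = _occupied_range(hist)
    t1 = _renyi_partial(p, P1, first, last, 0.5)
    t2 = _renyi_partial(p, P1, first, last, 1.0)
    t3 = _renyi_partial(p, P1, first, last, 2.0)
    ts = sorted([t1, t2, t3])
    t_star1, t_star2, t_star3 = ts
    if abs(t_star1 - t_star2) <= 5:
        if abs(t_star2 - t_star3) <= 5:
            beta1, beta2, beta3 = 1, 2, 1
        else:
            beta1, beta2, beta3 = 0, 1, 3
    else:
        if abs(t_star2 - t_star3) <= 5:
            beta1, beta2, beta3 = 3, 1, 0
        else:
            beta1, beta2, beta3 = 1, 2, 1
    omega = P1[t_star3] - P1[t_star1]
    opt = (
        t_star1 * (P1[t_star1] + 0.25 * omega * beta1)
        + 0.25 * t_star2 * omega * beta2
        + t_star3 * (1.0 - P1[t_star3] + 0.25 * omega * beta3)
    )
    return int(opt)


def _shanbhag(hist: np.ndarray) -> int:
    # minimize |fuzzy information of background - object|
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    first, last = _occupied_range(hist)
    best, best_ent = first, np.inf
    for t in range(first, last + 1):
        if P1[t] <= 0 or P2[t] <= 0:
            continue
        term = 0.5 / P1[t]
        ent_back = 0.0
        for ih in range(1, t + 1):
            arg = 1.0 - term * P1[ih - 1]
            if arg > 0:
                ent_back -= p[ih] * np.log(arg)
        ent_back *= term
        term = 0.5 / P2[t]
        ent_obj = 0.0
        for ih in range(t + 1, 256):
            arg = 1.0 - term * P2[ih]
            if arg > 0:
                ent_obj -= p[ih] * np.log(arg)
        ent_obj *= term
        tot = abs(ent_back - ent_obj)
        if tot < best_ent:
            best_ent, best = tot, t
    return best


def _triangle(hist: np.ndarray) -> int:
    # Zack: maximal distance between the histogram and the peak-to-tail chord
    data = hist.astype(np.float64).copy()
    lo = 0
    for i in range(256):
        if data[i] > 0:
            lo = i
            break
    if lo > 0:
        lo -= 1
    hi = 255
    for i in range(255, -1, -1):
        if data[i] > 0:
            hi = i
            break
    if hi < 255:
        hi += 1
    peak, dmax = 0, 0.0
    for i in range(256):
        if data[i] > dmax:
            dmax, peak = data[i], i
    inverted = False
    if (peak - lo) < (hi - peak):
        # long tail on the right: flip so the tail is on the left
        inverted = True
        data = data[::-1].copy()
        lo = 255 - hi
        peak = 255 - peak
    if lo == peak:
        return lo
    nx = data[peak]
    ny = float(lo - peak)
    d = np.sqrt(nx * nx + ny * ny)
    nx /= d
    ny /= d
    d = nx * lo + ny * data[lo]
    split, split_dist = lo, 0.0
    for i in range(lo + 1, peak + 1):
        nd = nx * i + ny * data[i] - d
        if nd > split_dist:
            split_dist, split = nd, i
    split -= 1
    return 255 - split if inverted else split


def _yen(hist: np.ndarray) -> int:
    # maximize Yen's maximum-correlation criterion
    p = hist / hist.sum()
    P1 = np.cumsum(p)
    P1_sq = np.cumsum(p**2)
    P2_sq = np.cumsum((p**2)[::-1])[::-1] - p**2  # sum over bins > t
    best, best_crit = 0, -np.inf
    for t in range(256):
        tail_sq = P2_sq[t] if t < 255 else 0.0
        crit = -(
            np.log(P1_sq[t] * tail_sq) if P1_sq[t] * tail_sq > 0 else 0.0
        ) + 2 * (
            np.log(P1[t] * (1.0 - P1[t])) if P1[t] * (1.0 - P1[t]) > 0 else 0.0
        )
        if crit > best_crit:
            best_crit, best = crit, t
    return best


THRESHOLD_METHODS: dict[str, callable] = {
    "Default": _default,
    "Huang": _huang,
    "Intermodes": _intermodes,
    "IsoData": _isodata,
    "Li": _li,
    "MaxEntropy": _max_entropy,
    "Mean": _mean,
    "MinError(I)": _min_error,
    "Minimum": _minimum,
    "Moments": _moments,
    "Otsu": _otsu,
    "Percentile": _percentile,
    "RenyiEntropy": _renyi_entropy,
    "Shanbhag": _shanbhag,
    "Triangle": _triangle,
    "Yen": _yen,
}


def auto_threshold(histogram: np.ndarray, method: str) -> int:
    """Compute a global threshold level from a 256-bin histogram.

    Parameters
    ----------
    histogram : array of 256 bin counts.
    method : one of the names in :data:`THRESHOLD_METHODS` (verbatim,
        e.g. ``"Otsu"``, ``"MinError(I)"``).

    Returns
    -------
    int level ``t`` in 0..255; pixels with intensity strictly above ``t``
    are foreground. Deterministic for a given histogram.
    """
    if method not in THRESHOLD_METHODS:
        raise ValueError(
            f"unknown threshold method '{method}'; valid methods: "
            + ", ".join(sorted(THRESHOLD_METHODS))
        )
    hist = _validate(histogram)
    t = int(THRESHOLD_METHODS[method](hist))
    return min(max(t, 0), 255)
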