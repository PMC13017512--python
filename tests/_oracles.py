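"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorised/blocked code paths: plain
per-site Python loops and textbook closed forms, so they can serve as
oracles for the production estimators.
"""

import math

import numpy as np

from admixkit.genodata import MISSING


def site_frequencies(panel, population):
    """Per-site allele frequency by explicit loops."""
    idx = [
        i
        for i, p in enumerate(panel.samples["population"])
        if p == population
    ]
    ploidy = panel.samples["ploidy"].to_numpy()
    freqs = []
    for s in range(panel.n_sites):
        num = den = 0
        for i in idx:
            c = int(panel.calls[s, i])
            if c != MISSING:
                num += c
                den += int(ploidy[i])
        freqs.append(num / den if den else math.nan)
    return freqs


def brute_d(panel, w, x, y, z):
    """D statistic via per-site loops, no blocking."""
    fw = site_frequencies(panel, w)
    fx = site_frequencies(panel, x)
    fy = site_frequencies(panel, y)
    fz = site_frequencies(panel, z)
    num = den = 0.0
    for a, b, c, d in zip(fw, fx, fy, fz):
        if any(math.isnan(v) for v in (a, b, c, d)):
            continue
        num += (a - b) * (c - d)
        den += (a + b - 2 * a * b) * (c + d - 2 * c * d)
    return num / den


def brute_f4(panel, a, b, c, d):
    """Unblocked mean of per-site f4 terms."""
    fa = site_frequencies(panel, a)
    fb = site_frequencies(panel, b)
    fc = site_frequencies(panel, c)
    fd = site_frequencies(panel, d)
    terms = [
        (p - q) * (r - s)
        for p, q, r, s in zip(fa, fb, fc, fd)
        if not any(math.isnan(v) for v in (p, q, r, s))
    ]
    return sum(terms) / len(terms)


def abba_baba_d(panel, w, x, y, z):
    """Site-pattern counting D for single-sample haploid populations.

    Counts sites where P1≠P2 and P3≠P4; BABA patterns (P1 matching P3)
    contribute +1 and ABBA patterns (P1 matching P4) −1.
    """
    iw = panel.population_indices(w)[0]
    ix = panel.population_indices(x)[0]
    iy = panel.population_indices(y)[0]
    iz = panel.population_indices(z)[0]
    baba = abba = 0
    for s in range(panel.n_sites):
        a, b, c, d = (int(panel.calls[s, i]) for i in (iw, ix, iy, iz))
        if MISSING in (a, b, c, d):
            continue
        if a != b and c != d:
            if a == c:
                baba += 1
            else:
                abba += 1
    return (baba - abba) / (baba + abba)


def law_of_cosines_km(lat1, lon1, lat2, lon2, radius=6371.0):
    """Spherical law-of-cosines great-circle distance."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    arg = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius * math.acos(min(1.0, max(-1.0, arg)))


def simple_mantel_r(A, B):
    """Pearson correlation of lower triangles, computed directly."""
    n = A.shape[0]
    xs, ys = [], []
    for i in range(n):
        for j in range(i):
            xs.append(A[i, j])
            ys.append(B[i, j])
    xs, ys = np.array(xs), np.array(ys)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    return float(xs @ ys / math.sqrt((xs @ xs) * (ys @ ys)))
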