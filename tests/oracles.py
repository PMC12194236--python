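"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — explicit Python-loop sums, direct
rotation-matrix construction, normal equations via lstsq — and shares no code
path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def rotate(points, theta_deg, about=(0.0, 0.0)):
    """Rotate (x, y) tuples CCW by theta about a pivot, via the rotation matrix."""
    t = math.radians(theta_deg)
    r = np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])
    about = np.asarray(about, dtype=float)
    return [tuple(r @ (np.asarray(p, dtype=float) - about) + about) for p in points]


def brute_mean_squares(values):
    """Two-way ANOVA mean squares by explicit sums (no numpy reductions)."""
    v = [[float(x) for x in row] for row in values]
    n, k = len(v), len(v[0])
    grand = sum(sum(row) for row in v) / (n * k)
    row_means = [sum(row) / k for row in v]
    col_means = [sum(v[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((v[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def brute_icc2k_estimate(values):
    """ICC(2,k) point estimate straight from the mean-squares definition."""
    n = len(values)
    msr, msc, mse = brute_mean_squares(values)
    return (msr - mse) / (msr + (msc - mse) / n)


def brute_bland_altman(x, y, multiplier=1.96):
    """Bias and limits of agreement by hand."""
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    bias = sum(d) / n
    sd = math.sqrt(sum((di - bias) ** 2 for di in d) / (n - 1))
    return bias, sd, bias - multiplier * sd, bias + multiplier * sd


def brute_ols(x, y):
    """Least-squares line via the normal equations (lstsq on the design matrix)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(xa), xa])
    (intercept, slope), *_ = np.linalg.lstsq(design, ya, rcond=None)
    resid = ya - design @ np.array([intercept, slope])
    sse = float(resid @ resid)
    sst = float(((ya - ya.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    see = math.sqrt(sse / (len(xa) - 2))
    return float(intercept), float(slope), r2, see
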