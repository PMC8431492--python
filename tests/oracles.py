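"""Independent brute-force oracles, kept deliberately naive.

These re-derive expected values from first principles (loops, textbook
formulas) and must stay independent of the package implementation paths
they are used to check.
"""

from __future__ import annotations

import math


def pearson_two_pass(x, y) -> float:
    """Textbook two-pass Pearson correlation with explicit loops."""
    n = len(x)
    assert n == len(y) and n >= 2
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sxx = syy = 0.0
    for xi, yi in zip(x, y):
        sxy += (xi - mx) * (yi - my)
        sxx += (xi - mx) ** 2
        syy += (yi - my) ** 2
    return sxy / math.sqrt(sxx * syy)


def acf_lag1_brute(s) -> float:
    """Lag-1 autocorrelation as Pearson over the overlapping pairs."""
    return pearson_two_pass(list(s[:-1]), list(s[1:]))


def paired_t_brute(before, after) -> tuple[float, float]:
    """Paired t statistic and two-tailed p from the textbook formula.

    p is computed by numerical integration of the Student-t density,
    independent of scipy.
    """
    d = [b - a for b, a in zip(before, after)]
    n = len(d)
    mean = sum(d) / n
    var = sum((di - mean) ** 2 for di in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t, 2.0 * _student_t_sf(abs(t), n - 1)


def _student_t_sf(t: float, df: int) -> float:
    """P(T > t) for Student t with df degrees of freedom, by Simpson quadrature.

    The polynomial tail is integrated exactly via the substitution w = 1/x,
    so no truncation error is incurred.
    """
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x: float) -> float:
        return c * (1.0 + x * x / df) ** (-(df + 1) / 2)

    def tail_integrand(w: float) -> float:
        # pdf(1/w) / w**2, written in a form finite at w = 0
        return (
            c * df ** ((df + 1) / 2) * w ** (df - 1)
            * (1.0 + w * w * df) ** (-(df + 1) / 2)
        )

    def simpson(f, a: float, b: float, n: int = 20000) -> float:
        h = (b - a) / n
        total = f(a) + f(b)
        for k in range(1, n):
            total += (4 if k % 2 else 2) * f(a + k * h)
        return total * h / 3.0

    split = max(t, 1.0)
    head = simpson(pdf, t, split) if split > t else 0.0
    tail = simpson(tail_integrand, 0.0, 1.0 / split)
    return head + tail


def averaged_variance_brute(s, w: int) -> float:
    """Windowed population variance mean, with explicit window loops."""
    n_windows = len(s) // w
    assert n_windows >= 1
    total = 0.0
    for i in range(n_windows):
        window = s[i * w : (i + 1) * w]
        m = sum(window) / w
        total += sum((v - m) ** 2 for v in window) / w
    return total / n_windows
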