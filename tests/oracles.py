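"""Independent brute-force oracles used by the test suite.

Everything here is written naively (python loops, math module scalars,
explicit formulas) and independently of the library's fast paths, so a
test comparing the two routes is a genuine dual computation.
"""

import math


def renyi_threshold_scan(histogram):
    """Exhaustive-scan maximum-Rényi-entropy threshold.

    Direct per-threshold evaluation of the three entropy objectives
    (α = 1/2, 1, 2) over every candidate grey level, followed by the
    three-estimate β-weight combination, all in plain python arithmetic.
    """
    data = [float(c) for c in histogram]
    total = sum(data)
    norm = [c / total for c in data]
    p1 = []
    run = 0.0
    for v in norm:
        run += v
        p1.append(run)
    p2 = [1.0 - p for p in p1]

    eps = 2.220446049250313e-16
    first_bin = 0
    for i, p in enumerate(p1):
        if p > eps:
            first_bin = i
            break
    last_bin = len(data) - 1
    for i in range(len(data) - 1, first_bin - 1, -1):
        if p2[i] > eps:
            last_bin = i
            break

    def scan(objective):
        best_t, best = first_bin, -math.inf
        for t in range(first_bin, last_bin + 1):
            v = objective(t)
            if v > best:
                best, best_t = v, t
        return best_t

    n = len(data)

    def shannon(t):
        ent_back = 0.0
        for i in range(0, t + 1):
            if data[i] != 0:
                ent_back -= (norm[i] / p1[t]) * math.log(norm[i] / p1[t])
        ent_obj = 0.0
        for i in range(t + 1, n):
            if data[i] != 0:
                ent_obj -= (norm[i] / p2[t]) * math.log(norm[i] / p2[t])
        return ent_back + ent_obj

    def alpha_half(t):
        ent_back = sum(math.sqrt(norm[i] / p1[t]) for i in range(0, t + 1))
        ent_obj = sum(math.sqrt(norm[i] / p2[t]) for i in range(t + 1, n))
        prod = ent_back * ent_obj
        return 2.0 * math.log(prod) if prod > 0 else 0.0

    def alpha_two(t):
        ent_back = sum((norm[i] / p1[t]) ** 2 for i in range(0, t + 1))
        ent_obj = sum((norm[i] / p2[t]) ** 2 for i in range(t + 1, n))
        prod = ent_back * ent_obj
        return -math.log(prod) if prod > 0 else 0.0

    t_star1 = scan(alpha_half)
    t_star2 = scan(shannon)
    t_star3 = scan(alpha_two)

    ts = sorted([t_star1, t_star2, t_star3])
    t_star1, t_star2, t_star3 = ts
    if abs(t_star1 - t_star2) <= 5:
        if abs(t_star2 - t_star3) <= 5:
            b1, b2, b3 = 1, 2, 1
        else:
            b1, b2, b3 = 0, 1, 3
    else:
        if abs(t_star2 - t_star3) <= 5:
            b1, b2, b3 = 3, 1, 0
        else:
            b1, b2, b3 = 1, 2, 1

    omega = p1[t_star3] - p1[t_star1]
    opt = (
        t_star1 * (p1[t_star1] + 0.25 * omega * b1)
        + 0.25 * t_star2 * omega * b2
        + t_star3 * (p2[t_star3] + 0.25 * omega * b3)
    )
    return int(math.floor(opt))


def aerodynamic_diameter_bisection(d_pa, f_v, chi, rho_p, rho_0, mfp_um, tol=1e-12):
    """Bisection solve of d_ae² C_c(d_ae) ρ₀ = d_ve² C_c(d_ve) ρ_p/χ."""

    def cc(d):
        kn = 2.0 * mfp_um / d
        return 1.0 + kn * (1.142 + 0.558 * math.exp(-0.999 / kn))

    d_ve = (6.0 * f_v / math.pi) ** (1.0 / 3.0) * d_pa
    rhs = d_ve**2 * cc(d_ve) * rho_p / chi

    def f(d_ae):
        return d_ae**2 * cc(d_ae) * rho_0 - rhs

    lo, hi = 1e-6, 1e5
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * mid:
            break
    return 0.5 * (lo + hi)
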