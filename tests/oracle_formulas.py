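"""Independent literal-formula oracles for every index.

Pure-Python loops, written directly from the textbook formulas and
sharing no code with the library, so oracle-vs-implementation agreement
is a genuine cross-check.
"""
import math


def _pos(counts):
    return [v for v in counts.values() if v > 0]


def o_richness(counts):
    return len(_pos(counts))


def o_total(counts):
    return sum(counts.values())


def o_shannon(counts):
    n = _pos(counts)
    N = sum(n)
    return -sum((x / N) * math.log(x / N) for x in n)


def o_simpson(counts):
    n = _pos(counts)
    N = sum(n)
    return sum((x / N) ** 2 for x in n)


def o_hill(counts):
    return (o_richness(counts), math.exp(o_shannon(counts)), 1.0 / o_simpson(counts))


def o_margalef(counts):
    return (o_richness(counts) - 1) / math.log(o_total(counts))


def o_gleason(counts):
    return o_richness(counts) / math.log(o_total(counts))


def o_menhinick(counts):
    return o_richness(counts) / math.sqrt(o_total(counts))


def o_odum(counts):
    return o_richness(counts) / math.log10(o_total(counts))


def o_brillouin(counts):
    # integer counts assumed
    n = [int(round(v)) for v in _pos(counts)]
    n = [x for x in n if x > 0]
    N = sum(n)
    return (math.lgamma(N + 1) - sum(math.lgamma(x + 1) for x in n)) / N


def o_mcintosh(counts):
    n = _pos(counts)
    N = sum(n)
    U = math.sqrt(sum(x * x for x in n))
    return (N - U) / (N - math.sqrt(N))


def o_camargo(counts):
    n = _pos(counts)
    N = sum(n)
    p = [x / N for x in n]
    S = len(p)
    total = 0.0
    for i in range(S):
        for j in range(i + 1, S):
            total += abs(p[i] - p[j])
    return 1.0 - total / S


def o_pie(counts):
    N = o_total(counts)
    return (N / (N - 1)) * (1.0 - o_simpson(counts))


def o_fisher_alpha(counts):
    """Bisection on S = alpha ln(1 + N/alpha)."""
    S, N = o_richness(counts), o_total(counts)
    lo, hi = 1e-6, 1e6
    for _ in range(200):
        mid = (lo + hi) / 2
        if mid * math.log(1 + N / mid) < S:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def o_chao2(presence):
    """presence: list of rows (units) of 0/1 over species."""
    m = len(presence)
    n_species = len(presence[0])
    occ = [sum(presence[u][s] for u in range(m)) for s in range(n_species)]
    s_obs = sum(1 for o in occ if o > 0)
    q1 = sum(1 for o in occ if o == 1)
    q2 = sum(1 for o in occ if o == 2)
    return s_obs + ((m - 1) / m) * q1 * (q1 - 1) / (2 * (q2 + 1))


def o_chao_single(counts):
    n = [int(round(v)) for v in _pos(counts)]
    n = [x for x in n if x > 0]
    f1 = sum(1 for x in n if x == 1)
    f2 = sum(1 for x in n if x == 2)
    return len(n) + f1 * (f1 - 1) / (2 * (f2 + 1))


def o_kothe(counts, s_ref):
    return 100.0 * (s_ref - o_richness(counts)) / s_ref


def o_evenness(counts):
    n = _pos(counts)
    S = len(n)
    H = o_shannon(counts)
    eH = math.exp(H)
    inv_lam = 1.0 / o_simpson(counts)
    return {
        "E1": H / math.log(S) if S > 1 else None,
        "E2": eH / S,
        "E3": (eH - 1) / (S - 1) if S > 1 else None,
        "E4": inv_lam / eH,
        "E5": (inv_lam - 1) / (eH - 1) if S > 1 else None,
        "simpson_evenness": inv_lam / S,
    }


def o_redundancy(counts):
    n = [int(round(v)) for v in _pos(counts)]
    n = [x for x in n if x > 0]
    S = len(n)
    if S == 1:
        return None
    N = sum(n)
    if N < S + 1:
        return None
    h_max = math.log(S)
    parts = [N - S + 1] + [1] * (S - 1)
    h_min = -sum((x / N) * math.log(x / N) for x in parts)
    if h_max - h_min < 1e-12:
        return None
    H = -sum((x / N) * math.log(x / N) for x in n)
    return (h_max - H) / (h_max - h_min)


def o_berger_parker(counts):
    n = _pos(counts)
    return max(n) / sum(n)


def o_mcnaughton(counts):
    n = sorted(_pos(counts), reverse=True)
    top2 = n[0] + (n[1] if len(n) > 1 else 0.0)
    return 100.0 * top2 / sum(n)
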