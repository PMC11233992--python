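"""Alpha-diversity, evenness and dominance indices with a named registry.

All indices operate on a single sample's abundance vector (ind·m⁻³).
Natural logarithms are used throughout (Shannon entropy in nats), with the
single exception of Odum's index which is defined on log₁₀.  Indices whose
formula requires integer individual counts (Brillouin, the single-sample
Chao estimator) round abundances half-to-even first and log a warning when
rounding changes a value.

Index values outside a formula's domain (e.g. Pielou's E1 for a
one-species sample) are reported as NaN, the table-level "undefined"
marker, and are excluded pairwise by downstream screening.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln

from .core import GOOD, AbundanceSample, IncidenceMatrix, SampleSet

logger = logging.getLogger("ecostatus")

DIVERSITY = "diversity"
EVENNESS = "evenness"
DOMINANCE = "dominance"
DEMO = "demo"

UP_IN_GOOD = "up_in_good"
UP_IN_NON_GOOD = "up_in_non_good"
DIRECTION_UNKNOWN = "unknown"


def _counts(counts) -> np.ndarray:
    """Positive abundance vector from a mapping or sequence."""
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("abundances must be finite and non-negative")
    return arr[arr > 0]


def _require_positive(arr: np.ndarray) -> np.ndarray:
    if arr.size == 0:
        raise ValueError("index undefined for an all-zero sample")
    return arr


def _round_integer(arr: np.ndarray) -> np.ndarray:
    """Round half-to-even for integer-count formulas; warn when lossy."""
    rounded = np.rint(arr)
    if not np.allclose(arr, rounded):
        logger.warning(
            "non-integer abundances rounded half-to-even for an "
            "integer-count index formula"
        )
    return rounded[rounded > 0]


# --- diversity --------------------------------------------------------------


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    n = _require_positive(_counts(counts))
    p = n / n.sum()
    return float(-(p * np.log(p)).sum())


def simpson_concentration(counts) -> float:
    """Simpson concentration lambda = sum p_i^2 (rises with dominance)."""
    n = _require_positive(_counts(counts))
    p = n / n.sum()
    return float((p**2).sum())


def hill_numbers(counts) -> tuple[float, float, float]:
    """Hill effective species numbers (N0, N1, N2).

    N0 is richness, N1 = exp(H) and N2 = 1/lambda; N0 >= N1 >= N2 >= 1.
    """
    n = _require_positive(_counts(counts))
    return (
        float(n.size),
        math.exp(shannon(n)),
        1.0 / simpson_concentration(n),
    )


def richness_ratios(counts) -> dict[str, float]:
    """Richness standardized by total abundance: Margalef (S-1)/ln N,
    Gleason S/ln N, Menhinick S/sqrt(N), Odum S/log10 N.  Requires N > 1."""
    n = _require_positive(_counts(counts))
    N = n.sum()
    if N <= 1:
        raise ValueError("richness ratios need total abundance N > 1")
    S = n.size
    return {
        "margalef": (S - 1) / math.log(N),
        "gleason": S / math.log(N),
        "menhinick": S / math.sqrt(N),
        "odum": S / math.log10(N),
    }


def brillouin(counts) -> float:
    """Brillouin diversity HB = (ln N! - sum ln n_i!)/N via log-gamma."""
    n = _round_integer(_require_positive(_counts(counts)))
    if n.size == 0:
        raise ValueError("all abundances rounded to zero")
    N = n.sum()
    return float((gammaln(N + 1) - gammaln(n + 1).sum()) / N)


def mcintosh_m(counts) -> float:
    """McIntosh's index M = (N - U)/(N - sqrt(N)) with U = sqrt(sum n_i^2)."""
    n = _require_positive(_counts(counts))
    N = n.sum()
    if N <= 1:
        raise ValueError("McIntosh's M needs total abundance N > 1")
    U = math.sqrt(float((n**2).sum()))
    return float((N - U) / (N - math.sqrt(N)))


def camargo(counts) -> float:
    """Camargo evenness-style diversity: 1 - sum_{i<j} |p_i - p_j| / S."""
    n = _require_positive(_counts(counts))
    p = n / n.sum()
    S = p.size
    diff = np.abs(p[:, None] - p[None, :])
    return float(1.0 - diff[np.triu_indices(S, k=1)].sum() / S)


def hurlbert_pie(counts) -> float:
    """Hurlbert's PIE = (N/(N-1)) (1 - sum p_i^2): probability that two
    randomly drawn individuals are different species."""
    n = _require_positive(_counts(counts))
    N = n.sum()
    if N <= 1:
        raise ValueError("PIE needs total abundance N > 1")
    return float(N / (N - 1) * (1.0 - simpson_concentration(n)))


def fisher_alpha(counts) -> float:
    """Fisher's log-series alpha: the unique a > 0 with S = a ln(1 + N/a).

    Solved by bracketed root-finding to |residual| < 1e-9; requires
    S >= 2 and N > S.
    """
    n = _require_positive(_counts(counts))
    S, N = n.size, float(n.sum())
    if S < 2 or N <= S:
        raise ValueError("Fisher's alpha needs S >= 2 and N > S")

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    lo, hi = 1e-10, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for valid S, N
            raise RuntimeError("Fisher's alpha bracket expansion failed")
    alpha = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    assert abs(f(alpha)) < 1e-9
    return float(alpha)


def chao2(incidence: IncidenceMatrix) -> float:
    """Bias-corrected Chao2 incidence-based minimum-richness estimator.

    S_obs + ((m-1)/m) q1 (q1-1) / (2 (q2+1)), with q1/q2 the species
    occurring in exactly one/two of the m sampling units.
    """
    pres = incidence.presence
    m = incidence.n_units
    if m < 1 or pres.size == 0:
        raise ValueError("Chao2 needs at least one sampling unit")
    occ = pres.sum(axis=0)
    s_obs = int((occ > 0).sum())
    if m == 1:
        raise ValueError("Chao2 needs >= 2 units; use chao_single per sample")
    q1 = int((occ == 1).sum())
    q2 = int((occ == 2).sum())
    return float(s_obs + (m - 1) / m * q1 * (q1 - 1) / (2.0 * (q2 + 1)))


def chao_single(counts) -> float:
    """Abundance-based single-sample analogue of Chao's estimator.

    S_obs + f1 (f1-1) / (2 (f2+1)) with f1/f2 the species whose rounded
    count equals 1/2.  Used when no replicate-unit incidence exists.
    """
    n = _round_integer(_require_positive(_counts(counts)))
    if n.size == 0:
        raise ValueError("all abundances rounded to zero")
    s_obs = n.size
    f1 = int((n == 1).sum())
    f2 = int((n == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def kothe_deficit(counts, reference_richness: int) -> float:
    """Kothe's species deficit, percent: 100 (S_ref - S)/S_ref.

    Rises with degradation; negative (logged) when the sample is richer
    than the reference.
    """
    if reference_richness < 1:
        raise ValueError("reference richness must be >= 1")
    S = _require_positive(_counts(counts)).size
    value = 100.0 * (reference_richness - S) / reference_richness
    if value < 0:
        logger.warning(
            "Kothe deficit negative: sample richness %d exceeds reference %d",
            S,
            reference_richness,
        )
    return float(value)


# --- evenness ---------------------------------------------------------------


def evenness_suite(counts) -> dict[str, float]:
    """Evenness ratios E1-E5, Simpson evenness and Patten's redundancy.

    E1 = H/ln S (Pielou's J'), E2 = e^H/S, E3 = (e^H - 1)/(S - 1),
    E4 = (1/lambda)/e^H, E5 = (1/lambda - 1)/(e^H - 1),
    simpson_evenness = (1/lambda)/S.  Redundancy = (Hmax - H)/(Hmax - Hmin)
    where Hmax = ln S and Hmin is the entropy of the most uneven integer
    partition (one species holding N-S+1 individuals, the rest 1 each).
    Out-of-domain ratios are NaN.
    """
    n = _require_positive(_counts(counts))
    S = n.size
    H = shannon(n)
    eH = math.exp(H)
    inv_lambda = 1.0 / simpson_concentration(n)
    out = {
        "E1": H / math.log(S) if S > 1 else math.nan,
        "E2": eH / S,
        "E3": (eH - 1.0) / (S - 1.0) if S > 1 else math.nan,
        "E4": inv_lambda / eH,
        "E5": (inv_lambda - 1.0) / (eH - 1.0) if S > 1 else math.nan,
        "simpson_evenness": inv_lambda / S,
    }
    out["redundancy"] = _redundancy(n, H)
    return out


def _redundancy(n: np.ndarray, H: float) -> float:
    S = n.size
    if S == 1:
        return math.nan
    h_max = math.log(S)
    N = float(np.rint(n.sum()))
    if N < S + 1:  # every species a singleton: Hmin == Hmax
        return math.nan
    # most uneven partition: (N-S+1, 1, ..., 1)
    big = N - S + 1
    h_min = -(big / N) * math.log(big / N) - (S - 1) * (1 / N) * math.log(1 / N)
    if h_max - h_min < 1e-12:
        return math.nan
    return float((h_max - H) / (h_max - h_min))


# --- dominance --------------------------------------------------------------


def dominance_suite(counts) -> dict[str, float]:
    """Berger-Parker (share of the single top species) and McNaughton
    (percent share of the top two)."""
    n = _require_positive(_counts(counts))
    N = n.sum()
    top = np.sort(n)[::-1]
    second = top[1] if top.size > 1 else 0.0
    return {
        "berger_parker": float(top[0] / N),
        "mcnaughton": float(100.0 * (top[0] + second) / N),
    }


def total_abundance(counts) -> float:
    """Total abundance, used as a demo (non-diversity) index."""
    if isinstance(counts, Mapping):
        arr = np.asarray(list(counts.values()), dtype=float)
    else:
        arr = np.asarray(counts, dtype=float)
    return float(arr.sum()) if arr.size else 0.0


# --- registry ---------------------------------------------------------------


@dataclass(frozen=True)
class IndexDefinition:
    """A named index: family, expected direction of change toward the
    good-status condition, and what it needs beyond the abundance vector."""

    name: str
    family: str
    expected_direction: str
    requires: str  # "abundance" | "incidence" | "reference_richness"
    func: Callable
    formula: str


def _simple(name, family, direction, func, formula):
    return IndexDefinition(name, family, direction, "abundance", func, formula)


def _build_registry() -> dict[str, IndexDefinition]:
    defs = [
        # diversity
        _simple("Margalef", DIVERSITY, UP_IN_GOOD,
                lambda c: richness_ratios(c)["margalef"], "(S-1)/ln N"),
        _simple("Gleason", DIVERSITY, UP_IN_GOOD,
                lambda c: richness_ratios(c)["gleason"], "S/ln N"),
        _simple("Menhinick", DIVERSITY, UP_IN_GOOD,
                lambda c: richness_ratios(c)["menhinick"], "S/sqrt(N)"),
        _simple("Odum", DIVERSITY, UP_IN_GOOD,
                lambda c: richness_ratios(c)["odum"], "S/log10 N"),
        _simple("Shannon", DIVERSITY, UP_IN_GOOD, shannon,
                "-sum p_i ln p_i"),
        _simple("HillN0", DIVERSITY, UP_IN_GOOD,
                lambda c: hill_numbers(c)[0], "S"),
        _simple("HillN1", DIVERSITY, UP_IN_GOOD,
                lambda c: hill_numbers(c)[1], "exp(H)"),
        _simple("HillN2", DIVERSITY, UP_IN_GOOD,
                lambda c: hill_numbers(c)[2], "1/sum p_i^2"),
        _simple("Simpson", DIVERSITY, UP_IN_NON_GOOD, simpson_concentration,
                "sum p_i^2"),
        _simple("Brillouin", DIVERSITY, UP_IN_GOOD, brillouin,
                "(ln N! - sum ln n_i!)/N"),
        _simple("M", DIVERSITY, UP_IN_GOOD, mcintosh_m,
                "(N-U)/(N-sqrt(N)), U = sqrt(sum n_i^2)"),
        _simple("CamargoDiversity", DIVERSITY, UP_IN_GOOD, camargo,
                "1 - sum_{i<j}|p_i-p_j|/S"),
        _simple("Pie", DIVERSITY, UP_IN_GOOD, hurlbert_pie,
                "(N/(N-1))(1 - sum p_i^2)"),
        _simple("FisherAlpha", DIVERSITY, UP_IN_GOOD, fisher_alpha,
                "S = alpha ln(1 + N/alpha)"),
        IndexDefinition("Chao2", DIVERSITY, UP_IN_GOOD, "incidence", chao2,
                        "S_obs + ((m-1)/m) q1(q1-1)/(2(q2+1))"),
        IndexDefinition("Kothe", DIVERSITY, UP_IN_NON_GOOD,
                        "reference_richness", kothe_deficit,
                        "100 (S_ref - S)/S_ref"),
        # evenness
        _simple("E1", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["E1"], "H/ln S (Pielou's J')"),
        _simple("E2", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["E2"], "e^H/S"),
        _simple("E3", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["E3"], "(e^H-1)/(S-1)"),
        _simple("E4", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["E4"], "(1/lambda)/e^H"),
        _simple("E5", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["E5"], "(1/lambda - 1)/(e^H - 1)"),
        _simple("SimpsonEvenness", EVENNESS, UP_IN_GOOD,
                lambda c: evenness_suite(c)["simpson_evenness"],
                "(1/lambda)/S"),
        _simple("Redundancy", EVENNESS, UP_IN_NON_GOOD,
                lambda c: evenness_suite(c)["redundancy"],
                "(Hmax - H)/(Hmax - Hmin)"),
        # dominance
        _simple("BergerParker", DOMINANCE, UP_IN_NON_GOOD,
                lambda c: dominance_suite(c)["berger_parker"], "max n_i / N"),
        _simple("McNaughton", DOMINANCE, UP_IN_NON_GOOD,
                lambda c: dominance_suite(c)["mcnaughton"],
                "100 (n(1)+n(2))/N"),
        # demo
        _simple("TotalAbundance", DEMO, DIRECTION_UNKNOWN, total_abundance,
                "sum n_i"),
    ]
    return {d.name: d for d in defs}


#: Default battery: 25 named diversity/evenness/dominance indices plus
#: total abundance as a demo index.  The name "Tu" from historical index
#: batteries has no canonical formula and is intentionally not shipped;
#: users may register their own definition for it.
REGISTRY: dict[str, IndexDefinition] = _build_registry()


@dataclass
class IndexTable:
    """Samples x indices value matrix with per-index metadata."""

    frame: pd.DataFrame  # index = sample_ids, columns = index names
    definitions: dict[str, IndexDefinition]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def index_names(self) -> list[str]:
        return list(self.frame.columns)

    def direction(self, name: str) -> str:
        return self.definitions[name].expected_direction


def resolve_registry(names: Sequence[str] | None = None) -> dict[str, IndexDefinition]:
    if names is None:
        return dict(REGISTRY)
    out = {}
    for name in names:
        if name not in REGISTRY:
            raise KeyError(
                f"unknown index {name!r}; valid names: {sorted(REGISTRY)}"
            )
        out[name] = REGISTRY[name]
    return out


def index_table(
    samples: SampleSet,
    registry: dict[str, IndexDefinition] | None = None,
    reference_richness: int | str = "auto",
) -> IndexTable:
    """Compute the index battery for every sample in a SampleSet.

    ``reference_richness``: Kothe's unpolluted baseline; ``"auto"`` uses
    the pooled richness of the samples labelled good.  Chao2 uses a
    sample's replicate-unit incidence matrix when present (classic
    multi-unit estimator), else the single-sample abundance analogue.
    Out-of-domain values are NaN, never exceptions.
    """
    registry = registry if registry is not None else dict(REGISTRY)
    s_ref: int | None = None
    if any(d.requires == "reference_richness" for d in registry.values()):
        if reference_richness == "auto":
            s_ref = samples.pooled_richness(GOOD)
            if s_ref == 0:
                raise ValueError(
                    "Kothe's reference richness is 'auto' but no sample is "
                    "labelled good; pass reference_richness explicitly"
                )
        else:
            s_ref = int(reference_richness)

    rows = []
    for sample in samples:
        counts = sample.positive_counts
        row = {}
        for name, d in registry.items():
            try:
                if d.requires == "incidence":
                    if sample.incidence is not None and sample.incidence.n_units > 1:
                        row[name] = chao2(sample.incidence)
                    else:
                        row[name] = chao_single(counts)
                elif d.requires == "reference_richness":
                    row[name] = d.func(counts, s_ref)
                else:
                    row[name] = d.func(counts)
            except ValueError:
                row[name] = math.nan
        rows.append(row)
    frame = pd.DataFrame(rows, index=pd.Index(samples.sample_ids, name="sample_id"))
    frame = frame[list(registry)]
    return IndexTable(frame=frame, definitions=registry)
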