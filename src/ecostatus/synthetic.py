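"""Synthetic mesozooplankton communities for two contrasting conditions.

The generator emulates the reference design of a coastal water-quality
study: a small "good"-status group of species-rich, even assemblages and
a larger "non-good" group of species-poor assemblages dominated by one
or two tolerant taxa whose cumulative share reaches or exceeds 80% of
total abundance.  Rank-abundance follows a geometric series p_i ∝
k(1-k)^(i-1), which gives direct analytic control of the top-two
cumulative share (k + k(1-k) = 0.84 at k = 0.6).  The dominant taxon
identity swaps with season, mirroring the warm-season cladoceran /
cold-season copepod alternation of the study system.

Counts are drawn as an integer multinomial on a lognormal total and
scaled by a nominal filtered volume of 1 m³, so integer-count index
formulas stay exact while units remain ind·m⁻³.  Each sample also gets
a replicate-unit incidence matrix (the total split multinomially across
units) so incidence-based estimation is exercised.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import COLD, GOOD, NON_GOOD, WARM, AbundanceSample, IncidenceMatrix, SampleSet

#: Shared taxon pool (the study system identified 86 copepod and
#: cladoceran taxa).  Rank 0 of the pool is the warm-season dominant,
#: rank 1 the cold-season dominant.
SPECIES_POOL_SIZE = 86
WARM_DOMINANT = "sp001"  # warm-season tolerant cladoceran analogue
COLD_DOMINANT = "sp002"  # cold-season tolerant copepod analogue


def _species_id(i: int) -> str:
    return f"sp{i + 1:03d}"


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults reproduce the reference design."""

    seed: int = 0
    n_good: int = 8
    n_non_good: int = 20
    richness_good: tuple[int, int] = (30, 45)
    richness_non_good: tuple[int, int] = (8, 15)
    dominance_k_good: float = 0.08
    dominance_k_non_good: float = 0.60
    total_abundance_median: float = 2000.0
    total_abundance_log_sd: float = 0.4
    season_mix: float = 0.5  # fraction of samples in the warm season
    replicate_units: int = 3

    def __post_init__(self) -> None:
        for k in (self.dominance_k_good, self.dominance_k_non_good):
            if not 0 < k < 1:
                raise ValueError("dominance parameter k must be in (0, 1)")
        for lo, hi in (self.richness_good, self.richness_non_good):
            if not 1 <= lo <= hi <= SPECIES_POOL_SIZE:
                raise ValueError("richness range must be within the species pool")
        if self.n_good < 0 or self.n_non_good < 0 or self.n_good + self.n_non_good < 1:
            raise ValueError("need at least one sample")
        if not 0 <= self.season_mix <= 1:
            raise ValueError("season_mix must be in [0, 1]")
        if self.replicate_units < 1:
            raise ValueError("replicate_units must be >= 1")


def rank_abundance(S: int, k: float) -> np.ndarray:
    """Geometric-series relative abundances p_i ∝ k(1-k)^(i-1), i=1..S.

    Strictly decreasing and renormalized to sum to 1.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not 0 < k < 1:
        raise ValueError("k must be in (0, 1)")
    p = k * (1 - k) ** np.arange(S)
    return p / p.sum()


def generate_sample(
    condition: str,
    season: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "s1",
) -> AbundanceSample:
    """Draw one sample for a condition (good/non_good) and season.

    Richness is uniform on the condition's range; the geometric series
    uses the condition's dominance parameter; the top rank is assigned
    to the season's dominant taxon and the remaining ranks to taxa drawn
    without replacement from the shared pool.
    """
    if condition == GOOD:
        lo, hi = config.richness_good
        k = config.dominance_k_good
    elif condition == NON_GOOD:
        lo, hi = config.richness_non_good
        k = config.dominance_k_non_good
    else:
        raise ValueError(f"unknown condition {condition!r}")
    S = int(rng.integers(lo, hi + 1))
    p = rank_abundance(S, k)

    dominant = WARM_DOMINANT if season == WARM else COLD_DOMINANT
    other = COLD_DOMINANT if season == WARM else WARM_DOMINANT
    pool = [
        _species_id(i)
        for i in range(SPECIES_POOL_SIZE)
        if _species_id(i) not in (dominant, other)
    ]
    rest = list(rng.choice(pool, size=S - 1, replace=False)) if S > 1 else []
    species = [dominant] + rest

    N = int(round(config.total_abundance_median
                  * np.exp(rng.normal(0.0, config.total_abundance_log_sd))))
    N = max(N, S)  # every drawn species can be represented
    counts_vec = rng.multinomial(N, p)

    # replicate-unit incidence: split each species' count across units
    units = [f"{sample_id}_u{j + 1}" for j in range(config.replicate_units)]
    unit_counts = np.zeros((config.replicate_units, S), dtype=int)
    for i, c in enumerate(counts_vec):
        unit_counts[:, i] = rng.multinomial(
            c, np.full(config.replicate_units, 1.0 / config.replicate_units)
        )
    present = counts_vec > 0
    incidence = IncidenceMatrix(
        units=units,
        species=[sp for sp, ok in zip(species, present) if ok],
        presence=(unit_counts > 0)[:, present],
    )
    counts = {sp: float(c) for sp, c in zip(species, counts_vec) if c > 0}
    return AbundanceSample(
        sample_id=sample_id,
        counts=counts,
        station="SYN-G" if condition == GOOD else "SYN-N",
        period="P-SYN",
        season=season,
        incidence=incidence,
    )


def generate_dataset(config: SyntheticConfig) -> SampleSet:
    """Generate the full labelled two-condition dataset.

    Seasons are interleaved deterministically to match ``season_mix``
    within each condition group.
    """
    rng = np.random.default_rng(config.seed)
    samples: list[AbundanceSample] = []
    labels: dict[str, str] = {}
    for condition, n, tag in (
        (GOOD, config.n_good, "good"),
        (NON_GOOD, config.n_non_good, "nongood"),
    ):
        n_warm = int(round(config.season_mix * n))
        for i in range(n):
            season = WARM if i < n_warm else COLD
            sid = f"{tag}_{i + 1:02d}"
            samples.append(generate_sample(condition, season, config, rng, sid))
            labels[sid] = condition
    return SampleSet(samples=samples, labels=labels)
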