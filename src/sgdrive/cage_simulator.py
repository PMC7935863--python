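"""Stochastic implementation of the multigeneration cage trials.

Each generation: (1) every adult female draws a mate from a multinomial over
male genotypes weighted by mating competitiveness; (2) each mated pair lays a
Poisson number of eggs proportional to the genotype-specific fecundity of
both parents; (3) surviving offspring genotypes follow a multinomial over
the pair's zygote distribution (egg death from B/B lethality and
egg-viability costs is drawn jointly); (4) offspring sex is binomial(1/2),
folded into the sexed genotype classes; (5) the next generation's adults and
the scored sample are drawn without replacement at the census target via
multivariate hypergeometric sampling, half scored and half passaged as in
the cage protocol.  Trajectories are bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genetics_core import (
    FEMALE,
    MALE,
    DriveParams,
    IndividualState,
    ModelConfig,
    fitness_weights,
    individual,
    marker_class,
    trans_het,
    zygote_distribution,
)

__all__ = [
    "CageProtocol",
    "CageTrajectory",
    "TRAJECTORY_COLUMNS",
    "default_seed_composition",
    "simulate_cage",
    "score_cage",
]

TRAJECTORY_COLUMNS = (
    "replicate",
    "generation",
    "n_scored",
    "n_sgd_pos",
    "n_cas9_pos",
    "n_sgd_cas9_pos",
    "n_neither",
)


def default_seed_composition(
    config: ModelConfig,
    n_het_f: int = 15,
    n_het_m: int = 15,
    n_wt_f: int = 45,
    n_wt_m: int = 45,
) -> Tuple[Tuple[Tuple[IndividualState, int], ...], Tuple[Tuple[IndividualState, int], ...]]:
    """Cage seeding: double-heterozygous (sGD/+; Cas9/+) adults plus
    wildtype, 15+15 : 45+45 by default (25% trans-heterozygote carriers,
    12.5% drive allele frequency)."""
    het_f = trans_het(config, FEMALE)
    het_m = trans_het(config, MALE)
    wt_f = individual("W", "W", cas9=0, sex=FEMALE, config=config)
    wt_m = individual("W", "W", cas9=0, sex=MALE, config=config)
    females = tuple(x for x in ((het_f, n_het_f), (wt_f, n_wt_f)) if x[1] > 0)
    males = tuple(x for x in ((het_m, n_het_m), (wt_m, n_wt_m)) if x[1] > 0)
    return females, males


@dataclass(frozen=True)
class CageProtocol:
    """Cage-trial protocol: seeded adults, census target and duration.

    ``census`` is the number of adults passaged each generation (an equal
    number is scored); ``seed_females``/``seed_males`` are (genotype, count)
    pairs.  ``eggs_per_female`` sets the Poisson egg mean; any value much
    larger than census/females gives equivalent post-hypergeometric
    dynamics.
    """

    seed_females: Tuple[Tuple[IndividualState, int], ...]
    seed_males: Tuple[Tuple[IndividualState, int], ...]
    census: int = 120
    n_generations: int = 20
    eggs_per_female: float = 50.0

    def __post_init__(self) -> None:
        if self.census < 2:
            raise ValueError("census must be at least 2")
        if any(c < 0 for _, c in self.seed_females + self.seed_males):
            raise ValueError("seed counts must be non-negative")
        if self.eggs_per_female <= 0:
            raise ValueError("Poisson egg mean must be positive")

    @classmethod
    def default(cls, config: ModelConfig, **kwargs) -> "CageProtocol":
        females, males = default_seed_composition(config)
        return cls(seed_females=females, seed_males=males, **kwargs)


@dataclass
class CageTrajectory:
    """Scored marker-class counts per replicate per generation."""

    data: pd.DataFrame
    protocol: Optional[CageProtocol] = None
    seed: Optional[int] = None
    extinct: Dict[int, int] = field(default_factory=dict)  # replicate -> last generation

    def replicates(self) -> Sequence[int]:
        return sorted(self.data["replicate"].unique().tolist())

    def class_counts(self, replicate: int, generation: int) -> Dict[str, int]:
        """Counts of the four scored classes (sgd_cas9, sgd_only, cas9_only,
        neither) for one replicate/generation row."""
        sel = self.data[
            (self.data["replicate"] == replicate)
            & (self.data["generation"] == generation)
        ]
        if sel.empty:
            raise ValueError(
                f"no scored row for replicate {replicate}, generation {generation}"
            )
        row = sel.iloc[0]
        both = int(row["n_sgd_cas9_pos"])
        return {
            "sgd_cas9": both,
            "sgd_only": int(row["n_sgd_pos"]) - both,
            "cas9_only": int(row["n_cas9_pos"]) - both,
            "neither": int(row["n_neither"]),
        }


@lru_cache(maxsize=200_000)
def _zygote_arrays(
    mother: IndividualState,
    father: IndividualState,
    params: DriveParams,
    config: ModelConfig,
) -> Tuple[Tuple[IndividualState, ...], Tuple[float, ...], float]:
    dist, mass = zygote_distribution(mother, father, params, config)
    states = tuple(dist.keys())
    return states, tuple(dist[s] for s in states), mass


def _score(counts_f: Counter, counts_m: Counter) -> Dict[str, int]:
    n = n_sgd = n_cas9 = n_both = n_neither = 0
    for counts in (counts_f, counts_m):
        for st, c in counts.items():
            sgd, cas9 = marker_class(st)
            n += c
            n_sgd += c * sgd
            n_cas9 += c * cas9
            n_both += c * (sgd and cas9)
            n_neither += c * (not sgd and not cas9)
    return {
        "n_scored": n,
        "n_sgd_pos": n_sgd,
        "n_cas9_pos": n_cas9,
        "n_sgd_cas9_pos": n_both,
        "n_neither": n_neither,
    }


def _hypergeom_sample(
    rng: np.random.Generator, counts: Counter, n_draw: int
) -> Counter:
    """Multivariate hypergeometric draw of ``n_draw`` individuals (all of
    them if fewer are available); the drawn individuals are removed from
    ``counts``."""
    states = list(counts.keys())
    avail = np.array([counts[s] for s in states], dtype=np.int64)
    total = int(avail.sum())
    if total <= n_draw:
        drawn = Counter({s: int(c) for s, c in zip(states, avail)})
        counts.clear()
        return drawn
    take = rng.multivariate_hypergeometric(avail, n_draw)
    drawn = Counter()
    for s, t in zip(states, take):
        if t:
            drawn[s] = int(t)
            counts[s] -= int(t)
            if counts[s] == 0:
                del counts[s]
    return drawn


def _simulate_replicate(
    protocol: CageProtocol,
    params: DriveParams,
    config: ModelConfig,
    rng: np.random.Generator,
    replicate: int,
) -> Tuple[List[dict], Optional[int]]:
    females = Counter({st: c for st, c in protocol.seed_females})
    males = Counter({st: c for st, c in protocol.seed_males})
    rows: List[dict] = []

    # G_0 row: the seeded adults themselves are the scored census
    row = _score(females, males)
    row.update(replicate=replicate, generation=0)
    rows.append(row)

    half = protocol.census // 2
    for gen in range(1, protocol.n_generations + 1):
        if not females or not males:
            return rows, gen - 1

        # (1) mate choice ~ multinomial over male genotypes x mating weight
        male_states = list(males.keys())
        weights = np.array(
            [males[s] * fitness_weights(s, params, config).mating for s in male_states]
        )
        if weights.sum() <= 0.0:
            return rows, gen - 1
        pmate = weights / weights.sum()

        offspring_f: Counter = Counter()
        offspring_m: Counter = Counter()
        for f_state, n_females in females.items():
            fec_f = fitness_weights(f_state, params, config).fecundity
            if fec_f <= 0.0:
                continue
            mates = rng.multinomial(n_females, pmate)
            for m_state, n_pairs in zip(male_states, mates):
                if n_pairs == 0:
                    continue
                fec_m = fitness_weights(m_state, params, config).fecundity
                if fec_m <= 0.0:
                    continue
                states, probs, mass = _zygote_arrays(f_state, m_state, params, config)
                if mass <= 0.0:
                    continue
                # (2) eggs ~ Poisson, (3) surviving genotypes ~ multinomial
                # with a joint death class of weight 1 - mass
                n_eggs = rng.poisson(protocol.eggs_per_female * fec_f * fec_m * n_pairs)
                if n_eggs == 0:
                    continue
                p = np.append(np.array(probs) * mass, max(1.0 - mass, 0.0))
                draw = rng.multinomial(n_eggs, p / p.sum())
                for st, c in zip(states, draw[:-1]):
                    if c:
                        (offspring_f if st.sex == FEMALE else offspring_m)[st] += int(c)

        if not offspring_f or not offspring_m:
            return rows, gen - 1

        # (5) sample next adults and the scored pool per sex at the census
        # target, without replacement
        adults_f = _hypergeom_sample(rng, offspring_f, half)
        adults_m = _hypergeom_sample(rng, offspring_m, half)
        scored_f = _hypergeom_sample(rng, offspring_f, half)
        scored_m = _hypergeom_sample(rng, offspring_m, half)

        row = _score(scored_f, scored_m)
        row.update(replicate=replicate, generation=gen)
        rows.append(row)
        females, males = adults_f, adults_m
    return rows, None


def simulate_cage(
    protocol: CageProtocol,
    params: DriveParams,
    config: ModelConfig,
    replicates: int = 1,
    seed: int = 0,
) -> CageTrajectory:
    """Run the stochastic cage trial.

    Returns a :class:`CageTrajectory` whose ``data`` frame has one row per
    replicate per generation (schema :data:`TRAJECTORY_COLUMNS`).  A
    replicate whose population goes extinct is truncated at its last viable
    generation and recorded in ``CageTrajectory.extinct``.
    """
    all_rows: List[dict] = []
    extinct: Dict[int, int] = {}
    ss = np.random.SeedSequence(seed)
    for rep, child in enumerate(ss.spawn(replicates)):
        rng = np.random.default_rng(child)
        rows, died_at = _simulate_replicate(protocol, params, config, rng, rep)
        all_rows.extend(rows)
        if died_at is not None:
            extinct[rep] = died_at
    data = pd.DataFrame(all_rows, columns=list(TRAJECTORY_COLUMNS))
    return CageTrajectory(data=data, protocol=protocol, seed=seed, extinct=extinct)


def score_cage(traj: CageTrajectory, generation: int, replicate: int = 0) -> Dict[str, int]:
    """Scored marker-class counts for one generation of one replicate.

    Deterministic given the trajectory; raises ``ValueError`` for a
    generation outside the recorded range.
    """
    return traj.class_counts(replicate, generation)
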