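"""Expected genotype-frequency recursion over discrete generations.

The mean-field backbone of the pipeline: adults mate by random union of
gametes, with mothers weighted by fecundity and fathers by mating
competitiveness; offspring pass through the zygote distribution (deposition +
viability filtering) and are renormalised each generation with an equal sex
ratio at birth.  The cage protocol controls census, not fecundity, so
absolute density is ignored (resource-saturated cage).

For speed the recursion is driven by a precomputed "inheritance cube"
``cube[mother, father, offspring]`` built once per parameter set from the
per-parent gamete vectors, so a full multigeneration trajectory costs a few
small matrix contractions.  This vectorised path is cross-checked in the test
suite against a direct summation over :func:`sgdrive.genetics_core.zygote_distribution`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .genetics_core import (
    ALLELES,
    FEMALE,
    MALE,
    DriveParams,
    Haplotype,
    IndividualState,
    ModelConfig,
    _drive_gametes,
    _egg_survival,
    _x_transmission,
    canonical,
    fitness_weights,
    genotype_code,
    is_active,
    marker_class,
)

__all__ = [
    "MARKER_CLASSES",
    "GenotypeFrequencies",
    "ExtinctionError",
    "StateSpace",
    "state_space",
    "next_generation",
    "marker_expectations",
    "trajectory_marker_expectations",
    "seed_frequencies",
]

#: Scored fluorescence classes, in canonical order.
MARKER_CLASSES: Tuple[str, ...] = ("sgd_cas9", "sgd_only", "cas9_only", "neither")


class ExtinctionError(RuntimeError):
    """Raised when the expected offspring mass of a generation is zero."""


def _class_label(state: IndividualState) -> str:
    sgd, cas9 = marker_class(state)
    if sgd and cas9:
        return "sgd_cas9"
    if sgd:
        return "sgd_only"
    if cas9:
        return "cas9_only"
    return "neither"


# ---------------------------------------------------------------------------
# genotype state space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateSpace:
    """Enumerated canonical genotype space for one model configuration."""

    config: ModelConfig
    females: Tuple[IndividualState, ...]
    males: Tuple[IndividualState, ...]
    f_index: Mapping[IndividualState, int] = field(hash=False, compare=False, default=None)
    m_index: Mapping[IndividualState, int] = field(hash=False, compare=False, default=None)

    @property
    def n_f(self) -> int:
        return len(self.females)

    @property
    def n_m(self) -> int:
        return len(self.males)


@lru_cache(maxsize=None)
def state_space(config: ModelConfig) -> StateSpace:
    """Enumerate every canonical genotype (drive pair x Cas9 x exposure) per sex."""
    females: List[IndividualState] = []
    males: List[IndividualState] = []
    seen = set()
    for a1, a2 in product(ALLELES, repeat=2):
        for c1, c2 in product((False, True), repeat=2):
            for sex in (FEMALE, MALE):
                if config.x_linked and sex == MALE and (c1 and c2):
                    continue
                for exp in (False, True):
                    st = canonical(
                        IndividualState((Haplotype(a1, c1), Haplotype(a2, c2)), sex, exp),
                        config,
                    )
                    if st in seen:
                        continue
                    seen.add(st)
                    (females if sex == FEMALE else males).append(st)
    key = lambda s: (genotype_code(s), s.maternal_exposure)
    females.sort(key=key)
    males.sort(key=key)
    return StateSpace(
        config,
        tuple(females),
        tuple(males),
        {s: i for i, s in enumerate(females)},
        {s: i for i, s in enumerate(males)},
    )


# ---------------------------------------------------------------------------
# inheritance cube
# ---------------------------------------------------------------------------

def _autosomal_gamete_classes() -> List[Haplotype]:
    return [Haplotype(a, c) for a in ALLELES for c in (False, True)]


def _deposition_matrix(classes: Sequence, d: float, allele_of) -> np.ndarray:
    """Linear operator on gamete classes: W -> B with probability d,
    everything else (including Cas9/X carriage) preserved."""
    n = len(classes)
    mat = np.zeros((n, n))
    idx = {c: i for i, c in enumerate(classes)}
    for i, c in enumerate(classes):
        if allele_of(c) == "W" and d > 0.0:
            mat[i, idx[_swap_allele(c, "B")]] += d
            if d < 1.0:
                mat[i, i] += 1.0 - d
        else:
            mat[i, i] = 1.0
    return mat


def _swap_allele(cls, allele):
    if isinstance(cls, Haplotype):
        return Haplotype(allele, cls.cas9)
    return (allele,) + tuple(cls[1:])


@dataclass
class InheritanceCube:
    """cube[f, m, o]: expected surviving-offspring distribution (not
    normalised; row mass = egg-to-survivor fraction) for each mother x father
    genotype pair, over the combined offspring index (females then males)."""

    space: StateSpace
    params: DriveParams
    cube: np.ndarray
    fecundity_f: np.ndarray  # per female state
    fecundity_m: np.ndarray  # per male state (scales pair egg output)
    mating_m: np.ndarray     # per male state

    @property
    def n_f(self) -> int:
        return self.space.n_f


def _build_cube_autosomal(space: StateSpace, params: DriveParams) -> np.ndarray:
    config = space.config
    classes = _autosomal_gamete_classes()
    ncls = len(classes)
    cidx = {c: i for i, c in enumerate(classes)}

    egg = np.zeros((space.n_f, ncls))
    for i, st in enumerate(space.females):
        for h, p in _drive_gametes(st, params, config).items():
            egg[i, cidx[h]] += p
    spm = np.zeros((space.n_m, ncls))
    for i, st in enumerate(space.males):
        for h, p in _drive_gametes(st, params, config).items():
            spm[i, cidx[h]] += p

    dep = _deposition_matrix(classes, params.d_dep, lambda c: c.allele)
    n_out = space.n_f + space.n_m

    cube = np.zeros((space.n_f, space.n_m, n_out))
    for active in (False, True):
        rows = [i for i, st in enumerate(space.females) if is_active(st) == active]
        if not rows:
            continue
        K = np.zeros((ncls * ncls, n_out))
        for ie, he in enumerate(classes):
            for isp, hs in enumerate(classes):
                for sex in (FEMALE, MALE):
                    st = canonical(
                        IndividualState((he, hs), sex, active), config
                    )
                    s = _egg_survival(st, params, config)
                    if s == 0.0:
                        continue
                    if sex == FEMALE:
                        o = space.f_index[st]
                    else:
                        o = space.n_f + space.m_index[st]
                    K[ie * ncls + isp, o] += 0.5 * s
        E = egg[rows] @ dep if active else egg[rows]
        S = spm @ dep if active else spm
        T = np.einsum("fe,ms->fmes", E, S).reshape(len(rows), space.n_m, ncls * ncls)
        cube[rows] = T @ K
    return cube


def _build_cube_x_linked(space: StateSpace, params: DriveParams) -> np.ndarray:
    """X-linked Cas9: egg classes (allele, egg-X-Cas9); sperm classes
    (allele, {Y, X without Cas9, X with Cas9}) — the sperm class fixes the
    offspring sex and the paternal X contribution."""
    config = space.config
    egg_classes = [(a, x) for a in ALLELES for x in (0, 1)]
    spm_classes = [(a, t) for a in ALLELES for t in ("Y", "X0", "X1")]
    eidx = {c: i for i, c in enumerate(egg_classes)}

    egg = np.zeros((space.n_f, len(egg_classes)))
    for i, st in enumerate(space.females):
        px = _x_transmission(st)
        for h, p in _drive_gametes(st, params, config).items():
            if px > 0.0:
                egg[i, eidx[(h.allele, 1)]] += p * px
            if px < 1.0:
                egg[i, eidx[(h.allele, 0)]] += p * (1.0 - px)

    sidx = {c: i for i, c in enumerate(spm_classes)}
    spm = np.zeros((space.n_m, len(spm_classes)))
    for i, st in enumerate(space.males):
        xtag = "X1" if st.cas9_count >= 1 else "X0"
        for h, p in _drive_gametes(st, params, config).items():
            spm[i, sidx[(h.allele, "Y")]] += 0.5 * p
            spm[i, sidx[(h.allele, xtag)]] += 0.5 * p

    dep_e = _deposition_matrix(egg_classes, params.d_dep, lambda c: c[0])
    dep_s = _deposition_matrix(spm_classes, params.d_dep, lambda c: c[0])
    n_out = space.n_f + space.n_m

    cube = np.zeros((space.n_f, space.n_m, n_out))
    ne, ns = len(egg_classes), len(spm_classes)
    for active in (False, True):
        rows = [i for i, st in enumerate(space.females) if is_active(st) == active]
        if not rows:
            continue
        K = np.zeros((ne * ns, n_out))
        for ie, (ae, xe) in enumerate(egg_classes):
            for isp, (asp, tag) in enumerate(spm_classes):
                if tag == "Y":
                    sex, n_cas9 = MALE, xe
                else:
                    sex, n_cas9 = FEMALE, xe + (1 if tag == "X1" else 0)
                st = canonical(
                    IndividualState(
                        (Haplotype(ae, n_cas9 >= 1), Haplotype(asp, n_cas9 >= 2)),
                        sex,
                        active,
                    ),
                    config,
                )
                s = _egg_survival(st, params, config)
                if s == 0.0:
                    continue
                o = space.f_index[st] if sex == FEMALE else space.n_f + space.m_index[st]
                K[ie * ns + isp, o] += s  # sex probability folded into sperm classes
        E = egg[rows] @ dep_e if active else egg[rows]
        S = spm @ dep_s if active else spm
        T = np.einsum("fe,ms->fmes", E, S).reshape(len(rows), space.n_m, ne * ns)
        cube[rows] = T @ K
    return cube


@lru_cache(maxsize=32)
def inheritance_cube(params: DriveParams, config: ModelConfig) -> InheritanceCube:
    """Build (and cache) the full mating cube plus fitness vectors."""
    space = state_space(config)
    if config.x_linked:
        cube = _build_cube_x_linked(space, params)
    else:
        cube = _build_cube_autosomal(space, params)
    fec_f = np.array(
        [fitness_weights(st, params, config).fecundity for st in space.females]
    )
    fec_m = np.array(
        [fitness_weights(st, params, config).fecundity for st in space.males]
    )
    mat_m = np.array(
        [fitness_weights(st, params, config).mating for st in space.males]
    )
    return InheritanceCube(space, params, cube, fec_f, fec_m, mat_m)


# ---------------------------------------------------------------------------
# frequency containers and the recursion
# ---------------------------------------------------------------------------

@dataclass
class GenotypeFrequencies:
    """Per-sex genotype frequency vectors (each sums to 1) at one generation."""

    female: Dict[IndividualState, float]
    male: Dict[IndividualState, float]
    generation: int = 0

    def validate(self, atol: float = 1e-10) -> None:
        for name, d in (("female", self.female), ("male", self.male)):
            if any(v < -atol for v in d.values()):
                raise ValueError(f"negative {name} frequency")
            if abs(sum(d.values()) - 1.0) > atol:
                raise ValueError(f"{name} frequencies do not sum to 1")


def seed_frequencies(
    female_counts: Mapping[IndividualState, float],
    male_counts: Mapping[IndividualState, float],
) -> GenotypeFrequencies:
    """Normalise seeded adult counts into a generation-0 frequency object."""
    tf = float(sum(female_counts.values()))
    tm = float(sum(male_counts.values()))
    if tf <= 0 or tm <= 0:
        raise ValueError("seed requires at least one adult of each sex")
    return GenotypeFrequencies(
        {k: v / tf for k, v in female_counts.items() if v > 0},
        {k: v / tm for k, v in male_counts.items() if v > 0},
        generation=0,
    )


def _vectors(freqs: GenotypeFrequencies, space: StateSpace) -> Tuple[np.ndarray, np.ndarray]:
    f = np.zeros(space.n_f)
    m = np.zeros(space.n_m)
    for st, p in freqs.female.items():
        f[space.f_index[canonical(st, space.config)]] += p
    for st, p in freqs.male.items():
        m[space.m_index[canonical(st, space.config)]] += p
    return f, m


def _step(
    f: np.ndarray, m: np.ndarray, cube: InheritanceCube
) -> Tuple[np.ndarray, np.ndarray]:
    """One generation of the recursion on raw vectors."""
    wm = m * cube.mating_m
    tot_m = wm.sum()
    if tot_m <= 0.0:
        raise ExtinctionError("no mating-competent males")
    pm = wm / tot_m
    # mother weight: frequency x her fecundity; father fecundity scales each
    # pair's egg output on top of mate choice
    wf = f * cube.fecundity_f
    pair = np.outer(wf, pm) * cube.fecundity_m[None, :]
    off = np.einsum("fm,fmo->o", pair, cube.cube)
    nf = cube.space.n_f
    off_f, off_m = off[:nf], off[nf:]
    if off_f.sum() <= 0.0 or off_m.sum() <= 0.0:
        raise ExtinctionError("expected offspring mass is zero")
    return off_f / off_f.sum(), off_m / off_m.sum()


def next_generation(
    freqs: GenotypeFrequencies, params: DriveParams, config: ModelConfig
) -> GenotypeFrequencies:
    """Advance the expected genotype frequencies by one discrete generation.

    Raises :class:`ExtinctionError` when the total offspring mass is zero
    (population-extinct signal).
    """
    cube = inheritance_cube(params, config)
    f, m = _vectors(freqs, cube.space)
    off_f, off_m = _step(f, m, cube)
    space = cube.space
    return GenotypeFrequencies(
        {space.females[i]: v for i, v in enumerate(off_f) if v > 0.0},
        {space.males[i]: v for i, v in enumerate(off_m) if v > 0.0},
        generation=freqs.generation + 1,
    )


# ---------------------------------------------------------------------------
# marker expectations and trajectories
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _class_matrices(config: ModelConfig) -> Tuple[np.ndarray, np.ndarray]:
    space = state_space(config)
    cls = {c: i for i, c in enumerate(MARKER_CLASSES)}
    Cf = np.zeros((space.n_f, 4))
    Cm = np.zeros((space.n_m, 4))
    for i, st in enumerate(space.females):
        Cf[i, cls[_class_label(st)]] = 1.0
    for i, st in enumerate(space.males):
        Cm[i, cls[_class_label(st)]] = 1.0
    return Cf, Cm


def marker_expectations(
    freqs: GenotypeFrequencies, config: ModelConfig
) -> Dict[str, float]:
    """Expected proportions of the four scored fluorescence classes
    (dominant-marker convention), averaging the two sexes equally."""
    space = state_space(config)
    f, m = _vectors(freqs, space)
    Cf, Cm = _class_matrices(config)
    probs = 0.5 * (f @ Cf) + 0.5 * (m @ Cm)
    return dict(zip(MARKER_CLASSES, probs.tolist()))


def trajectory_marker_expectations(
    seed: GenotypeFrequencies,
    params: DriveParams,
    config: ModelConfig,
    n_generations: int,
) -> np.ndarray:
    """Fast path used by the likelihood: propagate the recursion and return
    an ``(n_generations + 1, 4)`` array of marker-class expectations, row 0
    being the seeded adults."""
    cube = inheritance_cube(params, config)
    Cf, Cm = _class_matrices(config)
    f, m = _vectors(seed, cube.space)
    out = np.empty((n_generations + 1, 4))
    out[0] = 0.5 * (f @ Cf) + 0.5 * (m @ Cm)
    for g in range(1, n_generations + 1):
        f, m = _step(f, m, cube)
        out[g] = 0.5 * (f @ Cf) + 0.5 * (m @ Cm)
    return out
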