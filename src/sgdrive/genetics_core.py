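"""Two-locus split-drive inheritance rules.

A split gene drive (sGD) consists of a gRNA + recoded-rescue cassette inserted
into an essential gene, plus a separately inherited static Cas9 transgene.
When both elements co-occur in an individual ("active" genotypes), the wildtype
homolog of the drive locus can be cleaved in the germline and either converted
to a drive copy by homology-directed repair (HDR, "homing") or resolved by
non-homologous end joining (NHEJ) into an in-frame functional resistant allele
(R) or an out-of-frame loss-of-function allele (B).  Maternal deposition of
Cas9/gRNA ribonucleoprotein additionally mutagenises zygotic wildtype alleles
(lethal/sterile mosaicism) and sustains germline cleavage for one extra
generation in Cas9-less daughters of active mothers ("shadow drive").

This module encodes the allele/genotype state space, the per-meiosis gamete
distribution, the zygote distribution including deposition and viability
filtering, genotype-dependent fitness multipliers, and small arithmetic
helpers (transmission -> conversion).  Everything downstream (deterministic
recursion, stochastic cage simulation, likelihood) is built on these rules.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, Iterable, Mapping, NamedTuple, Optional, Tuple

__all__ = [
    "ALLELES",
    "FEMALE",
    "MALE",
    "Haplotype",
    "IndividualState",
    "DriveParams",
    "ModelConfig",
    "individual",
    "canonical",
    "genotype_code",
    "parse_genotype_code",
    "is_active",
    "gamete_distribution",
    "zygote_distribution",
    "fitness_weights",
    "marker_class",
    "transmission_to_conversion",
]

#: Drive-locus allele states.  W = wildtype (cleavable), D = sGD drive with
#: recoded rescue, R = functional in-frame resistant, B = non-functional
#: out-of-frame resistant.  D, R and B are permanently uncleavable.
ALLELES: Tuple[str, ...] = ("D", "W", "R", "B")
_ALLELE_RANK = {a: i for i, a in enumerate(ALLELES)}

FEMALE = "F"
MALE = "M"

TARGET_TYPES = ("viability", "fecundity")
CAS9_LOCATIONS = ("autosome_unlinked", "autosome_linked", "x_linked")


@dataclass(frozen=True)
class Haplotype:
    """One chromosome copy: drive-locus allele plus Cas9 carriage.

    For autosomal Cas9 configurations the ``cas9`` flag marks a Cas9 transgene
    on this chromosome copy (phase is meaningful only when the two loci are
    linked).  For X-linked Cas9 the flag marks a Cas9-bearing X chromosome
    travelling with this genome copy; males carry at most one.
    """

    allele: str
    cas9: bool = False

    def __post_init__(self) -> None:
        if self.allele not in _ALLELE_RANK:
            raise ValueError(f"unknown drive allele {self.allele!r}")

    @property
    def _key(self) -> Tuple[int, int]:
        return (_ALLELE_RANK[self.allele], 0 if self.cas9 else 1)


@dataclass(frozen=True)
class IndividualState:
    """Diploid two-locus genotype with sex and maternal-Cas9-exposure flag."""

    haplotypes: Tuple[Haplotype, Haplotype]
    sex: str
    maternal_exposure: bool = False

    def __post_init__(self) -> None:
        if self.sex not in (FEMALE, MALE):
            raise ValueError(f"sex must be {FEMALE!r} or {MALE!r}")
        if len(self.haplotypes) != 2:
            raise ValueError("an individual carries exactly two haplotypes")

    @property
    def alleles(self) -> Tuple[str, str]:
        return (self.haplotypes[0].allele, self.haplotypes[1].allele)

    @property
    def cas9_count(self) -> int:
        return sum(1 for h in self.haplotypes if h.cas9)

    @property
    def has_drive(self) -> bool:
        return "D" in self.alleles


@dataclass(frozen=True)
class ModelConfig:
    """Which of the four drive architectures is being modelled.

    ``target_type`` selects how loss-of-function homozygotes are culled:
    ``"viability"`` (B/B dies at the egg stage; rab5/rab11/prosalpha2 analogs)
    or ``"fecundity"`` (B/B is completely sterile; spo11 analog).
    ``cas9_location`` selects Cas9 transmission rules: freely assorting
    autosome, linked autosome (female recombination only), or X-linked.
    Marker scoring is dominant: an individual scores sGD+ with >=1 D allele
    and Cas9+ with >=1 Cas9 copy, matching fluorescence scoring.
    """

    target_type: str
    cas9_location: str

    def __post_init__(self) -> None:
        if self.target_type not in TARGET_TYPES:
            raise ValueError(f"target_type must be one of {TARGET_TYPES}")
        if self.cas9_location not in CAS9_LOCATIONS:
            raise ValueError(f"cas9_location must be one of {CAS9_LOCATIONS}")

    @property
    def linked(self) -> bool:
        return self.cas9_location == "autosome_linked"

    @property
    def x_linked(self) -> bool:
        return self.cas9_location == "x_linked"


def _check_unit(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value!r} outside [0, 1]")


@dataclass(frozen=True)
class DriveParams:
    """Cleavage, repair, deposition, linkage and fitness-cost parameters.

    All rates and costs are probabilities/fractions in [0, 1].

    q_f, q_m
        Probability that a germline W allele is cut, per parent sex, given an
        active genotype (drive + Cas9 allele).
    h_f, h_m
        Probability that a cut allele is repaired by HDR (copied to D), per
        parent sex.  HDR requires the homolog to carry D as template;
        otherwise all cuts resolve by NHEJ.
    fR_f, fR_m
        Probability that an NHEJ repair yields a functional in-frame allele
        (R) rather than a loss-of-function allele (B), per parent sex.
    d_dep
        Probability that a zygotic W allele is mosaically converted to B by
        maternally deposited Cas9/gRNA (active mothers only; no embryonic
        HDR).
    sigma_shadow
        Multiplier on q for Cas9-less but maternally exposed females (shadow
        drive); exposure lasts exactly one generation.
    r_linked
        Female recombination fraction between the drive locus and a linked
        autosomal Cas9 (males are achiasmatic: fraction 0).  Default 0.02
        (~2 cM).
    chrom_loss
        Linked configuration only: probability that a cut, non-HDR-repaired
        receiver haplotype is lost during meiosis (receiver-chromosome
        damage).
    cost_fecundity_f, cost_fecundity_m
        Fractional fecundity reductions of active individuals
        (fecundity-target configurations).
    cost_mating_m, cost_eggviability
        Fractional reductions in male mating competitiveness and egg
        viability of active individuals (viability-target configurations).

    Costs apply only to individuals carrying >=1 D allele *and* Cas9 activity
    (a Cas9 allele, or maternal exposure in females).
    """

    q_f: float = 0.0
    q_m: float = 0.0
    h_f: float = 0.0
    h_m: float = 0.0
    fR_f: float = 0.0
    fR_m: float = 0.0
    d_dep: float = 0.0
    sigma_shadow: float = 0.0
    r_linked: float = 0.02
    chrom_loss: float = 0.0
    cost_fecundity_f: float = 0.0
    cost_fecundity_m: float = 0.0
    cost_mating_m: float = 0.0
    cost_eggviability: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            _check_unit(name, getattr(self, name))

    def for_sex(self, sex: str) -> Tuple[float, float, float]:
        """(q, h, fR) for a parent of the given sex."""
        if sex == FEMALE:
            return (self.q_f, self.h_f, self.fR_f)
        return (self.q_m, self.h_m, self.fR_m)


# ---------------------------------------------------------------------------
# genotype construction and canonical form
# ---------------------------------------------------------------------------

def canonical(state: IndividualState, config: ModelConfig) -> IndividualState:
    """Return the canonical representative of a genotype.

    For the linked configuration phase matters, so haplotypes are simply
    sorted.  For unlinked and X-linked configurations Cas9 phase is
    meaningless: alleles are sorted and the Cas9 copy count is re-attached to
    the leading haplotypes, collapsing phase-equivalent states.
    """
    h1, h2 = state.haplotypes
    if config.linked:
        hs = tuple(sorted((h1, h2), key=lambda h: h._key))
    else:
        alleles = sorted((h1.allele, h2.allele), key=_ALLELE_RANK.__getitem__)
        n = h1.cas9 + h2.cas9
        if config.x_linked and state.sex == MALE and n > 1:
            raise ValueError("X-linked males carry at most one Cas9-bearing X")
        hs = (Haplotype(alleles[0], n >= 1), Haplotype(alleles[1], n >= 2))
    return replace(state, haplotypes=hs)


def individual(
    a1: str,
    a2: str,
    *,
    cas9: int = 0,
    sex: str = FEMALE,
    exposure: bool = False,
    config: Optional[ModelConfig] = None,
    phase: Optional[Tuple[bool, bool]] = None,
) -> IndividualState:
    """Convenience constructor.

    ``cas9`` is the Cas9 copy count (0-2); for the linked configuration pass
    ``phase`` to state which haplotype carries Cas9.  The result is canonical
    for ``config`` (unlinked if omitted).
    """
    if phase is None:
        if not 0 <= cas9 <= 2:
            raise ValueError("cas9 copy count must be 0, 1 or 2")
        phase = (cas9 >= 1, cas9 >= 2)
    st = IndividualState((Haplotype(a1, phase[0]), Haplotype(a2, phase[1])), sex, exposure)
    return canonical(st, config or ModelConfig("viability", "autosome_unlinked"))


def trans_het(
    config: ModelConfig, sex: str, exposure: bool = False
) -> IndividualState:
    """The drive-competent master genotype: sGD/+ with one Cas9 copy.

    For the linked configuration the Cas9 transgene rides the receiver (W)
    homolog, in trans to the drive — the phase produced by crossing a drive
    homozygote to a Cas9 line.
    """
    if config.linked:
        return individual("D", "W", phase=(False, True), sex=sex, config=config)
    return individual("D", "W", cas9=1, sex=sex, exposure=exposure, config=config)


def genotype_code(state: IndividualState) -> str:
    """Stable string code, e.g. ``"DW|C+"`` = D and W alleles, Cas9 in cis
    with the D copy.  One ``C``/``+`` symbol per haplotype."""
    a = "".join(h.allele for h in state.haplotypes)
    c = "".join("C" if h.cas9 else "+" for h in state.haplotypes)
    return f"{a}|{c}"


def parse_genotype_code(
    code: str,
    sex: str,
    exposure: bool = False,
    config: Optional[ModelConfig] = None,
) -> IndividualState:
    """Inverse of :func:`genotype_code` (canonicalised for ``config``)."""
    try:
        alleles, flags = code.split("|")
        assert len(alleles) == 2 and len(flags) == 2
        assert set(flags) <= {"C", "+"}
    except (ValueError, AssertionError):
        raise ValueError(f"malformed genotype code {code!r}") from None
    st = IndividualState(
        (Haplotype(alleles[0], flags[0] == "C"), Haplotype(alleles[1], flags[1] == "C")),
        sex,
        exposure,
    )
    return canonical(st, config or ModelConfig("viability", "autosome_unlinked"))


# ---------------------------------------------------------------------------
# activity, cleavage and fitness
# ---------------------------------------------------------------------------

def is_active(ind: IndividualState) -> bool:
    """True iff the individual can cleave: it carries the gRNA source (>=1 D
    allele) together with a Cas9 allele, or is a female whose mother was
    active (maternally deposited Cas9 protein — shadow drive)."""
    if not ind.has_drive:
        return False
    if ind.cas9_count >= 1:
        return True
    return ind.sex == FEMALE and ind.maternal_exposure


def _q_star(ind: IndividualState, params: DriveParams) -> float:
    """Effective germline cleavage probability for this parent."""
    if not ind.has_drive:
        return 0.0
    q = params.q_f if ind.sex == FEMALE else params.q_m
    if ind.cas9_count >= 1:
        return q
    if ind.sex == FEMALE and ind.maternal_exposure:
        return q * params.sigma_shadow
    return 0.0


class FitnessWeights(NamedTuple):
    fecundity: float
    mating: float
    egg_viability: float


def fitness_weights(
    ind: IndividualState, params: DriveParams, config: ModelConfig
) -> FitnessWeights:
    """(fecundity, male-mating, egg-viability) multipliers for a genotype.

    All multipliers are 1 unless the individual is active (drive + Cas9
    activity).  Fecundity-target configurations reduce the fecundity of
    active individuals by the sex-specific cost and make B/B homozygotes
    completely sterile.  Viability-target configurations reduce active male
    mating competitiveness and the viability of active eggs (the latter is
    applied inside :func:`zygote_distribution`; it is reported here for
    completeness).
    """
    fec = mate = eggv = 1.0
    if config.target_type == "fecundity" and ind.alleles == ("B", "B"):
        return FitnessWeights(0.0, 1.0, 1.0)
    if is_active(ind):
        if config.target_type == "fecundity":
            cost = params.cost_fecundity_f if ind.sex == FEMALE else params.cost_fecundity_m
            fec = 1.0 - cost
        else:
            if ind.sex == MALE:
                mate = 1.0 - params.cost_mating_m
            eggv = 1.0 - params.cost_eggviability
    return FitnessWeights(fec, mate, eggv)


def marker_class(state: IndividualState) -> Tuple[bool, bool]:
    """Dominant fluorescence scoring: (sGD+, Cas9+)."""
    return (state.has_drive, state.cas9_count >= 1)


# ---------------------------------------------------------------------------
# gametes
# ---------------------------------------------------------------------------

def _drive_gametes(
    ind: IndividualState, params: DriveParams, config: ModelConfig
) -> Dict[Haplotype, float]:
    """Drive-locus gamete distribution over (allele, autosomal-Cas9) classes.

    For the X-linked configuration the returned ``cas9`` flags are always
    False (Cas9 does not ride the drive chromosome); X transmission is
    handled by the caller.  Mass lost to receiver-chromosome destruction
    (``chrom_loss``, linked configuration) is renormalised away, which is the
    per-meiosis interpretation of chromosome loss.
    """
    q = _q_star(ind, params)
    _, h_hdr, fR = params.for_sex(ind.sex)
    if config.linked:
        r = params.r_linked if ind.sex == FEMALE else 0.0
        loss = params.chrom_loss
    elif config.x_linked:
        r = None  # Cas9 not on this chromosome
        loss = 0.0
    else:
        r = 0.5
        loss = 0.0

    out: Dict[Haplotype, float] = defaultdict(float)
    h1, h2 = ind.haplotypes
    for own, other in ((h1, h2), (h2, h1)):
        # Cas9 flag travelling with this chromatid (recombination fraction r)
        if r is None:
            cas9_opts = [(False, 1.0)]
        elif own.cas9 == other.cas9:
            cas9_opts = [(own.cas9, 1.0)]
        else:
            cas9_opts = [(own.cas9, 1.0 - r), (other.cas9, r)]
        # allele fate; only W is cleavable and HDR needs the homolog D template
        h_eff = h_hdr if other.allele == "D" else 0.0
        if own.allele == "W" and q > 0.0:
            nhej = q * (1.0 - h_eff)
            fates = [
                ("W", 1.0 - q),
                ("D", q * h_eff),
                ("R", nhej * (1.0 - loss) * fR),
                ("B", nhej * (1.0 - loss) * (1.0 - fR)),
            ]
        else:
            fates = [(own.allele, 1.0)]
        for allele, pa in fates:
            if pa == 0.0:
                continue
            for flag, pc in cas9_opts:
                if pc == 0.0:
                    continue
                out[Haplotype(allele, flag)] += 0.5 * pa * pc

    total = sum(out.values())
    if total <= 0.0:
        raise ValueError("all gametes lost; check chrom_loss/parameters")
    return {h: p / total for h, p in out.items()}


def _x_transmission(ind: IndividualState) -> float:
    """Probability that a transmitted X chromosome carries Cas9 (X-linked
    configuration).  Females: copies/2.  Males: the flag of their single X."""
    if ind.sex == FEMALE:
        return ind.cas9_count / 2.0
    return 1.0 if ind.cas9_count >= 1 else 0.0


def gamete_distribution(
    ind: IndividualState, params: DriveParams, config: ModelConfig
) -> Dict[Haplotype, float]:
    """Probability table over transmitted haplotypes.

    For autosomal configurations the ``cas9`` flag is the Cas9 allele carried
    by the gamete.  For the X-linked configuration the flag marks a
    Cas9-bearing X accompanying the gamete: for males this is marginalised
    over X- and Y-bearing sperm (a Cas9 father transmits Cas9 with his X in
    half of the sperm); sex linkage of Cas9 to daughters is resolved in
    :func:`zygote_distribution`.
    """
    drive = _drive_gametes(ind, params, config)
    if not config.x_linked:
        return dict(drive)
    px = _x_transmission(ind) * (1.0 if ind.sex == FEMALE else 0.5)
    out: Dict[Haplotype, float] = defaultdict(float)
    for h, p in drive.items():
        if px > 0.0:
            out[Haplotype(h.allele, True)] += p * px
        if px < 1.0:
            out[Haplotype(h.allele, False)] += p * (1.0 - px)
    return dict(out)


# ---------------------------------------------------------------------------
# zygotes
# ---------------------------------------------------------------------------

def _deposition_fates(allele: str, d: float) -> Iterable[Tuple[str, float]]:
    # embryonic deposition performs NHEJ only: W -> B with probability d
    if allele == "W" and d > 0.0:
        if d >= 1.0:
            return (("B", 1.0),)
        return (("W", 1.0 - d), ("B", d))
    return ((allele, 1.0),)


def _egg_survival(
    state: IndividualState, params: DriveParams, config: ModelConfig
) -> float:
    """Probability that a zygote of this genotype survives the egg stage."""
    if config.target_type == "viability":
        if state.alleles == ("B", "B") or set(state.alleles) == {"B"}:
            return 0.0
        if is_active(state):
            return 1.0 - params.cost_eggviability
    return 1.0


def zygote_distribution(
    mother: IndividualState,
    father: IndividualState,
    params: DriveParams,
    config: ModelConfig,
) -> Tuple[Dict[IndividualState, float], float]:
    """Offspring genotype distribution for one mating pair, pre-census.

    Combines the parental gamete distributions; if the mother is active, each
    zygotic W allele is independently converted to B with probability
    ``d_dep`` (maternal deposition, NHEJ only).  Viability-target
    configurations then remove B/B genotypes (death at the egg stage) and
    weight active genotypes by ``1 - cost_eggviability``; fecundity-target
    configurations cull nothing at the egg stage (B/B individuals survive but
    are sterile).  Offspring ``maternal_exposure`` is set iff the mother was
    active.  Sex is assigned 1/2 : 1/2 (for X-linked Cas9, daughters receive
    the father's X).

    Returns ``(distribution, survival_mass)`` where the distribution is
    renormalised over survivors and ``survival_mass`` is the surviving
    fraction of eggs.  Zero surviving mass returns ``({}, 0.0)``.
    """
    if mother.sex != FEMALE or father.sex != MALE:
        raise ValueError("zygote_distribution expects a (female, male) pair")
    m_active = is_active(mother)
    d = params.d_dep if m_active else 0.0

    eggs = _drive_gametes(mother, params, config)
    sperm = _drive_gametes(father, params, config)

    if config.x_linked:
        px_egg = _x_transmission(mother)
        dad_x = father.cas9_count >= 1
        egg_x_opts = [(1, px_egg), (0, 1.0 - px_egg)]
        # sperm determine sex: X-bearing (daughter, carries dad's Cas9 state)
        # or Y-bearing (son)
        sex_opts = [(FEMALE, 0.5), (MALE, 0.5)]
    else:
        egg_x_opts = [(0, 1.0)]
        sex_opts = [(FEMALE, 0.5), (MALE, 0.5)]

    raw: Dict[IndividualState, float] = defaultdict(float)
    for he, pe in eggs.items():
        for hs, ps in sperm.items():
            base = pe * ps
            if base == 0.0:
                continue
            for ae, pae in _deposition_fates(he.allele, d):
                for asp, pas in _deposition_fates(hs.allele, d):
                    w = base * pae * pas
                    for sex, psx in sex_opts:
                        if config.x_linked:
                            for nx_egg, pxe in egg_x_opts:
                                if pxe == 0.0:
                                    continue
                                n_cas9 = nx_egg + (1 if (sex == FEMALE and dad_x) else 0)
                                st = individual(
                                    ae, asp, cas9=n_cas9, sex=sex,
                                    exposure=m_active, config=config,
                                )
                                raw[st] += w * psx * pxe
                        else:
                            st = canonical(
                                IndividualState(
                                    (Haplotype(ae, he.cas9), Haplotype(asp, hs.cas9)),
                                    sex,
                                    m_active,
                                ),
                                config,
                            )
                            raw[st] += w * psx

    surv: Dict[IndividualState, float] = {}
    mass = 0.0
    for st, p in raw.items():
        s = _egg_survival(st, params, config)
        if s > 0.0:
            surv[st] = surv.get(st, 0.0) + p * s
            mass += p * s
    if mass <= 0.0:
        return ({}, 0.0)
    return ({st: p / mass for st, p in surv.items()}, mass)


# ---------------------------------------------------------------------------
# transmission arithmetic
# ---------------------------------------------------------------------------

class ConversionResult(NamedTuple):
    conversion: float  # clipped at 0 for sub-Mendelian inputs
    raw: float         # 2*inheritance - 1, unclipped


def transmission_to_conversion(inheritance_fraction: float) -> ConversionResult:
    """Convert a marker inheritance fraction to a germline conversion rate.

    Under the identity inheritance = (1 + conversion)/2 (half of gametes
    carry the drive by Mendelian segregation, plus converted homologs), a
    transmission of 0.648 implies a conversion of 0.296 (~30%) and Mendelian
    transmission (0.5) implies 0.
    """
    if not 0.0 <= inheritance_fraction <= 1.0:
        raise ValueError("inheritance fraction must lie in [0, 1]")
    raw = 2.0 * inheritance_fraction - 1.0
    return ConversionResult(max(raw, 0.0), raw)
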