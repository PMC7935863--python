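"""Generators for every input the pipeline consumes.

Cage-trial trajectories, per-vial single-cross F2 scoring tables and
amplicon read sets are generated with the statistical structure the
analysis assumes (multinomial mate choice and offspring genotypes, Poisson
egg production, hypergeometric census sampling, binomial per-vial counts,
per-base substitution sequencing errors), so every stage of the pipeline is
testable without downloads.  A :class:`ScenarioTruth` bundles a ground-truth
parameterisation with the protocol that produced the data, and regeneration
is bit-identical given the master seed.

The scenario library ships four truths mirroring the four modelled drive
architectures (rab5-, spo11-, prosalpha2-cis- and rab11/X-like), with
drive efficacies initialised from published single-cross transmission
means and fitness costs at the published MAP estimates; they are emulations
for testing, not measurements.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .allele_audit import TargetLocus
from .cage_simulator import CageProtocol, CageTrajectory, simulate_cage
from .genetics_core import (
    FEMALE,
    MALE,
    DriveParams,
    IndividualState,
    ModelConfig,
    genotype_code,
    individual,
    marker_class,
    parse_genotype_code,
    trans_het,
    zygote_distribution,
)

__all__ = [
    "ScenarioTruth",
    "SCENARIOS",
    "make_scenario",
    "generate_cage_dataset",
    "generate_single_cross_dataset",
    "generate_amplicon_reads",
    "demo_locus",
    "apply_deletion",
    "apply_insertion",
    "drive_read",
    "default_mixture",
]


# ---------------------------------------------------------------------------
# scenario truths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioTruth:
    """Ground truth for one synthetic study: model configuration, drive
    parameters, cage protocol, single-cross design, sequencing error rate
    and the master RNG seed."""

    name: str
    config: ModelConfig
    params: DriveParams
    protocol: CageProtocol
    n_vials: int = 30
    f2_per_vial: int = 60
    error_rate: float = 0.001
    seed: int = 20210305

    def to_dict(self) -> dict:
        def seed_rows(pairs):
            return [
                {
                    "genotype_code": genotype_code(st),
                    "sex": st.sex,
                    "exposure": st.maternal_exposure,
                    "count": int(c),
                }
                for st, c in pairs
            ]

        return {
            "name": self.name,
            "config": asdict(self.config),
            "params": asdict(self.params),
            "protocol": {
                "seed_females": seed_rows(self.protocol.seed_females),
                "seed_males": seed_rows(self.protocol.seed_males),
                "census": self.protocol.census,
                "n_generations": self.protocol.n_generations,
                "eggs_per_female": self.protocol.eggs_per_female,
            },
            "n_vials": self.n_vials,
            "f2_per_vial": self.f2_per_vial,
            "error_rate": self.error_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioTruth":
        config = ModelConfig(**d["config"])

        def seed_pairs(rows):
            return tuple(
                (
                    parse_genotype_code(r["genotype_code"], r["sex"], r["exposure"], config),
                    int(r["count"]),
                )
                for r in rows
            )

        proto = d["protocol"]
        protocol = CageProtocol(
            seed_females=seed_pairs(proto["seed_females"]),
            seed_males=seed_pairs(proto["seed_males"]),
            census=proto["census"],
            n_generations=proto["n_generations"],
            eggs_per_female=proto["eggs_per_female"],
        )
        return cls(
            name=d["name"],
            config=config,
            params=DriveParams(**d["params"]),
            protocol=protocol,
            n_vials=d["n_vials"],
            f2_per_vial=d["f2_per_vial"],
            error_rate=d["error_rate"],
            seed=d["seed"],
        )


def _scenario(name, config, params, n_generations=20, **kwargs) -> ScenarioTruth:
    protocol = CageProtocol.default(config, n_generations=n_generations)
    return ScenarioTruth(name=name, config=config, params=params, protocol=protocol, **kwargs)


def _rab5_like() -> ScenarioTruth:
    # viability target, freely assorting autosomal Cas9.  Cleavage and HDR
    # are split so that (i) transmission (1 + q h)/2 matches the published
    # single-cross midpoints (96.2% female / 79.8% male) and (ii) the NHEJ
    # gamete rate q(1 - h) matches the published resistant-allele load
    # (in-frame indels 1.2% of all F2 alleles = 34.5% of NHEJ events, so
    # ~7% of drive-parent gametes carry an indel).  The fitted MAP fitness
    # cost (4.8%) is assigned to the egg-viability channel, the phenotype
    # the hatchability assays measured.
    return _scenario(
        "rab5-like",
        ModelConfig("viability", "autosome_unlinked"),
        DriveParams(
            q_f=0.994, q_m=0.666, h_f=0.930, h_m=0.895,
            fR_f=0.345, fR_m=0.345,
            d_dep=0.9, sigma_shadow=0.3,
            cost_eggviability=0.048,
        ),
    )


def _spo11_like() -> ScenarioTruth:
    # fecundity target (sterile mosaicism); transmission midpoints 79.1% /
    # 67.1%, with the NHEJ gamete rate pinned by in-frame indels at 7.7% of
    # total F2 alleles and few frameshifts (in-frame ~0.8 of NHEJ).  Most
    # in-frame indels at this locus disrupt the adjacent catalytic residues,
    # so the *functional* NHEJ fraction is low (0.1); non-functional
    # in-frame alleles behave as sterile-when-homozygous (B).  The MAP
    # fitness cost (11.3%) enters through female fecundity, the
    # egg-production channel of the stochastic model.
    return _scenario(
        "spo11-like",
        ModelConfig("fecundity", "autosome_unlinked"),
        DriveParams(
            q_f=0.775, q_m=0.535, h_f=0.751, h_m=0.640,
            fR_f=0.10, fR_m=0.10,
            d_dep=0.9, sigma_shadow=0.3,
            cost_fecundity_f=0.113,
        ),
    )


def _prosalpha2_cis_like() -> ScenarioTruth:
    # Cas9 linked ~2 cM to the drive locus on the receiver chromosome.
    # Apparent transmission >99% together with 35-40% receiver-marker
    # transmission is reproduced by moderate HDR plus near-certain loss of
    # cut, non-HDR-repaired receiver chromatids (renormalised meiosis);
    # MAP cost in cis 27.5% on the egg-viability channel
    return _scenario(
        "prosalpha2-cis-like",
        ModelConfig("viability", "autosome_linked"),
        DriveParams(
            q_f=1.0, q_m=1.0, h_f=0.55, h_m=0.55, fR_f=0.5, fR_m=0.5,
            d_dep=0.95, sigma_shadow=0.3, r_linked=0.02, chrom_loss=0.98,
            cost_eggviability=0.275,
        ),
    )


def _rab11_x_like() -> ScenarioTruth:
    # X-linked Cas9, viability target; transmission midpoints 98.1% / 77.8%
    # with the NHEJ gamete rate pinned by in-frame indels at 1.2% of total
    # alleles (63% of indels in frame); most in-frame alleles functional
    # apart from the 13% altering the prenylation cysteines; MAP cost 0
    return _scenario(
        "rab11-x-like",
        ModelConfig("viability", "x_linked"),
        DriveParams(
            q_f=0.999, q_m=0.593, h_f=0.962, h_m=0.936, fR_f=0.55, fR_m=0.55,
            d_dep=0.5, sigma_shadow=0.3,
        ),
    )


SCENARIOS = {
    "rab5-like": _rab5_like,
    "spo11-like": _spo11_like,
    "prosalpha2-cis-like": _prosalpha2_cis_like,
    "rab11-x-like": _rab11_x_like,
}


def make_scenario(name: str, **overrides) -> ScenarioTruth:
    """Instantiate a library scenario, optionally overriding truth fields."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    truth = SCENARIOS[name]()
    return replace(truth, **overrides) if overrides else truth


# ---------------------------------------------------------------------------
# cage and single-cross datasets
# ---------------------------------------------------------------------------

def generate_cage_dataset(
    truth: ScenarioTruth,
    replicates: int = 3,
    out_dir: Optional[Path] = None,
) -> CageTrajectory:
    """Simulate cage trajectories under the truth; optionally write the
    trajectory CSV plus a ``truth.json`` sidecar for round-trip testing."""
    traj = simulate_cage(
        truth.protocol, truth.params, truth.config, replicates=replicates, seed=truth.seed
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        traj.data.to_csv(out_dir / f"{truth.name}_trajectory.csv", index=False)
        (out_dir / f"{truth.name}_truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2)
        )
    return traj


def _master_cross(truth: ScenarioTruth, parent_sex: str) -> Tuple[IndividualState, IndividualState]:
    cfg = truth.config
    if parent_sex == FEMALE:
        mother = trans_het(cfg, FEMALE)
        father = individual("W", "W", cas9=0, sex=MALE, config=cfg)
    else:
        mother = individual("W", "W", cas9=0, sex=FEMALE, config=cfg)
        father = trans_het(cfg, MALE)
    return mother, father


def generate_single_cross_dataset(
    truth: ScenarioTruth,
    designs: Tuple[str, ...] = (FEMALE, MALE),
    out: Optional[Path] = None,
) -> pd.DataFrame:
    """Per-vial F2 marker-count table from single master x wildtype crosses.

    For each vial, F2 counts are drawn multinomially from the zygote
    marker-class probabilities of the specified master parent (a
    trans-heterozygous sGD/+; Cas9/+ individual) crossed to wildtype.  The
    ``designs`` tuple selects master-female and/or master-male vials.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 17]))
    rows: List[dict] = []
    vial = 0
    for parent_sex in designs:
        mother, father = _master_cross(truth, parent_sex)
        dist, _mass = zygote_distribution(mother, father, truth.params, truth.config)
        states = list(dist.keys())
        probs = np.array([dist[s] for s in states])
        sgd = np.array([marker_class(s)[0] for s in states])
        cas9 = np.array([marker_class(s)[1] for s in states])
        for _ in range(truth.n_vials):
            counts = rng.multinomial(truth.f2_per_vial, probs)
            n = counts.sum()
            n_sgd = int(counts[sgd].sum())
            n_cas9 = int(counts[cas9].sum())
            n_both = int(counts[sgd & cas9].sum())
            rows.append(
                {
                    "vial": vial,
                    "parent_sex": parent_sex,
                    "n_f2": int(n),
                    "n_sgd_pos": n_sgd,
                    "n_cas9_pos": n_cas9,
                    "n_sgd_cas9_pos": n_both,
                    "n_neither": int(n - n_sgd - n_cas9 + n_both),
                    "sgd_inheritance": n_sgd / n,
                    "cas9_inheritance": n_cas9 / n,
                }
            )
            vial += 1
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, index=False)
    return df


# ---------------------------------------------------------------------------
# amplicon reads and the synthetic demonstration locus
# ---------------------------------------------------------------------------

def demo_locus() -> TargetLocus:
    """A fully synthetic 180-bp demonstration amplicon (not a deposited
    construct sequence): reading frame 0, cut site at position 99,
    prenylation-style critical cysteine codons 32-33 immediately 5' of the
    cut, and a recoded diagnostic subsequence for drive alleles."""
    rng = random.Random(4221)
    codons = []
    aas = {}
    for i in range(60):
        if i in (31, 32):  # codons 32 and 33 (1-based): TGC/TGT cysteines
            codons.append("TGC" if i == 31 else "TGT")
            continue
        codons.append(rng.choice(
            ["GCT", "GAA", "CTG", "AAA", "GTT", "ACC", "GAT", "TTC", "CAG", "ATC",
             "CGT", "AGC", "CCA", "TAC", "GGT", "AAC", "CAT", "TGG"]
        ))
    ref = "".join(codons)
    return TargetLocus(
        name="demo-synthetic",
        reference=ref,
        cut_site=99,
        frame_offset=0,
        critical_codons=(32, 33),
        drive_signature="GACGTTCAAGCTGGCCGTTAAGGCACC",
    )


def apply_deletion(locus: TargetLocus, start: int, length: int) -> str:
    """Allele sequence with ``length`` bases deleted from ``start``."""
    ref = locus.reference
    if not 0 <= start < start + length <= len(ref):
        raise ValueError("deletion outside the amplicon")
    return ref[:start] + ref[start + length:]


def apply_insertion(locus: TargetLocus, position: int, insert: str) -> str:
    """Allele sequence with ``insert`` added at ``position``."""
    ref = locus.reference
    if not 0 <= position <= len(ref):
        raise ValueError("insertion outside the amplicon")
    return ref[:position] + insert.upper() + ref[position:]


def drive_read(locus: TargetLocus) -> str:
    """A read diagnostic for the drive allele (carries the recoded
    signature at the cut site)."""
    if not locus.drive_signature:
        raise ValueError("locus has no drive signature")
    c = locus.cut_site
    return locus.reference[:c] + locus.drive_signature + locus.reference[c:]


def default_mixture(locus: TargetLocus) -> Dict[str, float]:
    """A plausible post-drive NHEJ mixture at the demonstration locus."""
    return {
        locus.reference: 0.55,
        apply_deletion(locus, locus.cut_site - 3, 3): 0.20,   # in-frame
        apply_deletion(locus, locus.cut_site - 1, 2): 0.15,   # frameshift
        apply_insertion(locus, locus.cut_site, "A"): 0.10,    # frameshift ins
    }


_PHRED = "!\"#$%&'()*+,-./0123456789:;<=>?@ABCDEFGHI"


def generate_amplicon_reads(
    mixture: Mapping[str, float],
    n_reads: int,
    error_rate: float = 0.001,
    seed: int = 0,
    out: Optional[Path] = None,
) -> List[Tuple[str, str]]:
    """Sample reads from an allele mixture with per-base substitution errors.

    ``mixture`` maps allele sequences to proportions (must sum to 1).
    Returns ``(read_id, sequence)`` pairs; if ``out`` is given, also writes
    a FASTQ with constant Phred+33 qualities implied by the error rate.
    ``n_reads = 0`` yields an empty, valid FASTQ.
    """
    props = np.array(list(mixture.values()), dtype=float)
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("mixture proportions must be non-negative and sum to 1")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error rate must lie in [0, 1)")
    alleles = list(mixture.keys())
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, props) if n_reads else np.zeros(len(alleles), int)

    base_idx = {b: i for i, b in enumerate("ACGT")}
    reads: List[Tuple[str, str]] = []
    rid = 0
    for allele, c in zip(alleles, counts):
        if c == 0:
            continue
        arr = np.array([base_idx[b] for b in allele.upper()], dtype=np.int8)
        block = np.tile(arr, (c, 1))
        if error_rate > 0.0:
            mask = rng.random(block.shape) < error_rate
            # substitute uniformly among the three other bases
            shift = rng.integers(1, 4, size=block.shape)
            block = np.where(mask, (block + shift) % 4, block)
        lut = np.array(list("ACGT"))
        for row in block:
            reads.append((f"read_{rid}", "".join(lut[row])))
            rid += 1
    if out is not None:
        q = 40 if error_rate <= 0.0 else min(40, int(round(-10 * np.log10(error_rate))))
        qchar = _PHRED[q]
        with open(out, "w") as fh:
            for name, seq in reads:
                fh.write(f"@{name}\n{seq}\n+\n{qchar * len(seq)}\n")
    return reads
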