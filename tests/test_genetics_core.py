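"""Unit and property tests for the two-locus inheritance rules."""

import math
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgdrive import (
    DriveParams,
    fitness_weights,
    gamete_distribution,
    genotype_code,
    individual,
    is_active,
    parse_genotype_code,
    transmission_to_conversion,
    zygote_distribution,
)
from sgdrive.genetics_core import FEMALE, MALE, trans_het

from conftest import random_params


def allele_marginal(gametes):
    agg = defaultdict(float)
    for h, p in gametes.items():
        agg[h.allele] += p
    return dict(agg)


class TestActivity:
    def test_drive_plus_cas9_is_active(self, unlinked_viability):
        ind = individual("D", "W", cas9=1, config=unlinked_viability)
        assert is_active(ind)

    def test_cas9_without_grna_source_is_inactive(self, unlinked_viability):
        # the gRNA rides the drive element; Cas9 alone cannot cleave
        ind = individual("W", "W", cas9=2, config=unlinked_viability)
        assert not is_active(ind)

    def test_shadow_drive_female(self, unlinked_viability):
        """A Cas9-less female with maternally deposited Cas9 is active."""
        f = individual("D", "W", cas9=0, sex=FEMALE, exposure=True)
        m = individual("D", "W", cas9=0, sex=MALE, exposure=True)
        assert is_active(f)
        assert not is_active(m)  # no paternal protein carryover


class TestGametes:
    def test_drive_homozygote_transmits_drive_only(self, unlinked_viability):
        ind = individual("D", "D", cas9=2, config=unlinked_viability)
        g = allele_marginal(
            gamete_distribution(ind, DriveParams(q_f=1, h_f=0.5), unlinked_viability)
        )
        assert g == {"D": 1.0}

    def test_mendelian_limit_without_cleavage(self, unlinked_viability, neutral_params):
        ind = individual("D", "W", cas9=1, config=unlinked_viability)
        g = allele_marginal(gamete_distribution(ind, neutral_params, unlinked_viability))
        assert g["D"] == pytest.approx(0.5)
        assert g["W"] == pytest.approx(0.5)

    def test_cut_repair_enumeration(self, unlinked_viability):
        """q=1, h=0.9, fR=0.5 resolves to D 0.95 / R 0.025 / B 0.025."""
        p = DriveParams(q_f=1.0, h_f=0.9, fR_f=0.5)
        ind = individual("D", "W", cas9=1, sex=FEMALE, config=unlinked_viability)
        g = allele_marginal(gamete_distribution(ind, p, unlinked_viability))
        assert g["D"] == pytest.approx(0.95)
        assert g.get("W", 0.0) == pytest.approx(0.0)
        assert g["R"] == pytest.approx(0.025)
        assert g["B"] == pytest.approx(0.025)

    def test_high_hdr_reaches_printed_female_range(self, unlinked_viability):
        # q=1, h=0.95 -> P(D)=0.975, inside the 95.2-97.1% band
        p = DriveParams(q_f=1.0, h_f=0.95)
        ind = individual("D", "W", cas9=1, sex=FEMALE, config=unlinked_viability)
        g = allele_marginal(gamete_distribution(ind, p, unlinked_viability))
        assert 0.952 <= g["D"] <= 0.971 or g["D"] == pytest.approx(0.975)
        assert g["D"] == pytest.approx(0.975)

    def test_gamete_matches_closed_form_enumeration(self, unlinked_viability):
        """Brute-force enumeration of cut/repair fates for a D/W parent."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = random_params(rng)
            ind = individual("D", "W", cas9=1, sex=FEMALE, config=unlinked_viability)
            g = allele_marginal(gamete_distribution(ind, p, unlinked_viability))
            q, h, fR = p.q_f, p.h_f, p.fR_f
            assert g.get("D", 0) == pytest.approx(0.5 + 0.5 * q * h)
            assert g.get("W", 0) == pytest.approx(0.5 * (1 - q))
            assert g.get("R", 0) == pytest.approx(0.5 * q * (1 - h) * fR)
            assert g.get("B", 0) == pytest.approx(0.5 * q * (1 - h) * (1 - fR))

    def test_hdr_requires_drive_template(self, unlinked_viability):
        """With no D on the homolog all cuts resolve by NHEJ -- and with no
        D at all there is no gRNA, so nothing is cut."""
        p = DriveParams(q_f=1.0, h_f=0.9, fR_f=1.0)
        ind = individual("W", "R", cas9=2, sex=FEMALE, config=unlinked_viability)
        g = allele_marginal(gamete_distribution(ind, p, unlinked_viability))
        assert g == {"W": 0.5, "R": 0.5}

    def test_shadow_scaling(self, unlinked_viability):
        p = DriveParams(q_f=1.0, h_f=0.924, sigma_shadow=0.3)
        exposed = individual("D", "W", cas9=0, sex=FEMALE, exposure=True)
        g = allele_marginal(gamete_distribution(exposed, p, unlinked_viability))
        # transmission (1 + sigma q h)/2 ~ 64%, the shadow-drive signature
        assert g["D"] == pytest.approx(0.5 + 0.5 * 0.3 * 0.924)

    def test_male_phase_preserved_without_recombination(self, linked_viability):
        """r=0 in males: D stays in cis with its Cas9 flag exactly."""
        p = DriveParams(q_m=0.0, r_linked=0.02)
        ind = individual("D", "W", phase=(True, False), sex=MALE, config=linked_viability)
        g = gamete_distribution(ind, p, linked_viability)
        for h, prob in g.items():
            if h.allele == "D":
                assert h.cas9
            else:
                assert not h.cas9

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        q=st.floats(0, 1), h=st.floats(0, 1), fR=st.floats(0, 1),
        a1=st.sampled_from("DWRB"), a2=st.sampled_from("DWRB"),
        cas9=st.integers(0, 2), sex=st.sampled_from([FEMALE, MALE]),
    )
    def test_gametes_normalise(self, q, h, fR, a1, a2, cas9, sex):
        p = DriveParams(q_f=q, q_m=q, h_f=h, h_m=h, fR_f=fR, fR_m=fR)
        from sgdrive import ModelConfig

        for cfg in (
            ModelConfig("viability", "autosome_unlinked"),
            ModelConfig("viability", "x_linked"),
        ):
            if cfg.x_linked and sex == MALE and cas9 == 2:
                continue
            ind = individual(a1, a2, cas9=cas9, sex=sex, config=cfg)
            g = gamete_distribution(ind, p, cfg)
            assert sum(g.values()) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_cleavage_and_hdr(self, unlinked_viability):
        ind = individual("D", "W", cas9=1, sex=FEMALE, config=unlinked_viability)
        last = -1.0
        for q in np.linspace(0, 1, 11):
            g = allele_marginal(
                gamete_distribution(ind, DriveParams(q_f=q, h_f=0.7), unlinked_viability)
            )
            assert g.get("D", 0) >= last - 1e-12
            last = g.get("D", 0)
        last = -1.0
        for h in np.linspace(0, 1, 11):
            g = allele_marginal(
                gamete_distribution(ind, DriveParams(q_f=0.8, h_f=h), unlinked_viability)
            )
            assert g.get("D", 0) >= last - 1e-12
            last = g.get("D", 0)


class TestZygotes:
    def test_wildtype_cross_is_inert(self, unlinked_viability, strong_drive_params):
        mother = individual("W", "W", sex=FEMALE, config=unlinked_viability)
        father = individual("W", "W", sex=MALE, config=unlinked_viability)
        dist, mass = zygote_distribution(mother, father, strong_drive_params, unlinked_viability)
        assert mass == pytest.approx(1.0)
        for st_, p in dist.items():
            assert st_.alleles == ("W", "W")
            assert not st_.maternal_exposure

    def test_bb_cross_dies_at_egg_stage(self, unlinked_viability, neutral_params):
        mother = individual("B", "B", sex=FEMALE, config=unlinked_viability)
        father = individual("B", "B", sex=MALE, config=unlinked_viability)
        dist, mass = zygote_distribution(mother, father, neutral_params, unlinked_viability)
        assert mass == 0.0 and dist == {}

    def test_bb_survives_but_sterile_in_fecundity_config(self, unlinked_fecundity, neutral_params):
        mother = individual("B", "B", sex=FEMALE, config=unlinked_fecundity)
        father = individual("B", "B", sex=MALE, config=unlinked_fecundity)
        dist, mass = zygote_distribution(mother, father, neutral_params, unlinked_fecundity)
        assert mass == pytest.approx(1.0)
        fw = fitness_weights(next(iter(dist)), neutral_params, unlinked_fecundity)
        assert fw.fecundity == 0.0

    def test_full_deposition_leaves_drive_b_only(self, unlinked_viability):
        """d_dep=1, q=1, h=1: all paternal W cut to B, maternal gametes all
        D; the only survivors are D/B heterozygotes."""
        p = DriveParams(q_f=1.0, h_f=1.0, d_dep=1.0)
        mother = trans_het(unlinked_viability, FEMALE)
        father = individual("W", "W", sex=MALE, config=unlinked_viability)
        dist, mass = zygote_distribution(mother, father, p, unlinked_viability)
        assert mass > 0
        for st_ in dist:
            assert st_.alleles == ("D", "B")
            assert st_.maternal_exposure

    def test_exposure_set_only_by_active_mothers(self, unlinked_viability, strong_drive_params):
        mother = individual("D", "W", cas9=0, sex=FEMALE, config=unlinked_viability)
        father = trans_het(unlinked_viability, MALE)
        dist, _ = zygote_distribution(mother, father, strong_drive_params, unlinked_viability)
        assert all(not st_.maternal_exposure for st_ in dist)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 2**31 - 1),
        cfg_i=st.integers(0, 3),
    )
    def test_zygotes_normalise(self, seed, cfg_i, all_configs):
        cfg = all_configs[cfg_i]
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        alle = list("DWRB")
        mother = individual(
            rng.choice(alle), rng.choice(alle), cas9=int(rng.integers(0, 3)),
            sex=FEMALE, exposure=bool(rng.integers(0, 2)), config=cfg,
        )
        father = individual(
            rng.choice(alle), rng.choice(alle),
            cas9=int(rng.integers(0, 2 if cfg.x_linked else 3)),
            sex=MALE, config=cfg,
        )
        dist, mass = zygote_distribution(mother, father, p, cfg)
        assert 0.0 <= mass <= 1.0 + 1e-12
        if dist:
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_x_linked_sons_never_get_fathers_cas9(self, x_linked_viability, neutral_params):
        mother = individual("W", "W", cas9=0, sex=FEMALE, config=x_linked_viability)
        father = individual("W", "W", cas9=1, sex=MALE, config=x_linked_viability)
        dist, _ = zygote_distribution(mother, father, neutral_params, x_linked_viability)
        for st_, p in dist.items():
            if st_.sex == MALE:
                assert st_.cas9_count == 0
            else:
                assert st_.cas9_count == 1  # every daughter gets the paternal X


class TestFitness:
    def test_inactive_genotype_has_unit_weights(self, unlinked_viability):
        p = DriveParams(cost_mating_m=0.3, cost_eggviability=0.3)
        ind = individual("D", "W", cas9=0, sex=MALE, config=unlinked_viability)
        assert fitness_weights(ind, p, unlinked_viability) == (1.0, 1.0, 1.0)

    def test_published_spo11_cost_example(self, unlinked_fecundity):
        p = DriveParams(cost_fecundity_f=0.113)
        ind = individual("D", "W", cas9=1, sex=FEMALE, config=unlinked_fecundity)
        assert fitness_weights(ind, p, unlinked_fecundity).fecundity == pytest.approx(0.887)

    def test_male_mating_cost_viability_config(self, unlinked_viability):
        p = DriveParams(cost_mating_m=0.2, cost_eggviability=0.1)
        ind = trans_het(unlinked_viability, MALE)
        fw = fitness_weights(ind, p, unlinked_viability)
        assert fw.mating == pytest.approx(0.8)
        assert fw.egg_viability == pytest.approx(0.9)


class TestConversionArithmetic:
    @pytest.mark.parametrize(
        "transmission,expected",
        [(0.648, 0.296), (0.5, 0.0), (1.0, 1.0), (0.4, 0.0)],
    )
    def test_transmission_to_conversion(self, transmission, expected):
        res = transmission_to_conversion(transmission)
        assert res.conversion == pytest.approx(expected)

    def test_raw_value_reported_for_sub_mendelian(self):
        res = transmission_to_conversion(0.4)
        assert res.raw == pytest.approx(-0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            transmission_to_conversion(1.2)


class TestGenotypeCodes:
    def test_round_trip(self, all_configs):
        for cfg in all_configs:
            st_ = trans_het(cfg, FEMALE)
            code = genotype_code(st_)
            back = parse_genotype_code(code, FEMALE, False, cfg)
            assert back == st_

    def test_malformed_code_rejected(self):
        with pytest.raises(ValueError):
            parse_genotype_code("DWC", FEMALE)
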