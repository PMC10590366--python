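import numpy as np
import pandas as pd
import pytest

from famphase import hmm
from famphase.data import ModelParams, Pedigree, SiteTable
from famphase.evaluate import dichotomize, evaluate_family
from famphase.likelihoods import (
    embryo_read_likelihood_table,
    genotype_prior_table,
    read_likelihood_table,
)
from famphase.phasing import (
    FamilyPhasingModel,
    child_emissions,
    emission_child_mode,
    emission_grandparent_mode,
    run_phasing,
    switch_probs,
    transition_matrix,
    transmit_weights,
    grandparent_emissions,
    _joint_stack,
    _two_state_stack,
)

from oracles import child_emission_oracle, grandparent_emission_oracle

PARAMS = ModelParams()


class TestTransitions:
    def test_zero_distance_is_identity(self):
        np.testing.assert_allclose(transition_matrix(0.0, 1), np.eye(2))

    def test_infinite_distance_limit(self):
        np.testing.assert_allclose(transition_matrix(50.0, 2), np.full((2, 2), 0.5), atol=1e-12)

    def test_haldane_closed_form(self):
        r = transition_matrix(0.01, 1)[0, 1]
        assert r == pytest.approx((1 - np.exp(-0.02)) / 2)
        assert r == pytest.approx(0.009901, abs=5e-7)

    def test_rows_are_stochastic(self):
        for d in (0.0, 1e-4, 0.3):
            for n in (1, 2):
                np.testing.assert_allclose(transition_matrix(d, n).sum(axis=1), 1.0)

    def test_joint_stack_is_tensor_product(self):
        r_m, r_f = np.array([0.01]), np.array([0.2])
        joint = _joint_stack(r_m, r_f)[0]
        expected = np.kron(transition_matrix(0, 1) * 0 + _two_state_stack(r_m)[0],
                           _two_state_stack(r_f)[0])
        np.testing.assert_allclose(joint, np.kron(_two_state_stack(r_m)[0], _two_state_stack(r_f)[0]))
        assert joint.shape == (4, 4)
        np.testing.assert_allclose(joint.sum(axis=1), 1.0)


def _ped_child():
    return Pedigree(mother_id="m", father_id="f", embryos=["e"],
                    reference_mode="child", reference_child_id="c")


def _ped_gp(n_gp=2):
    return Pedigree(mother_id="m", father_id="f", embryos=["e"],
                    reference_mode="grandparent",
                    grandparents={"maternal": ["g1", "g2"][:n_gp]})


class TestChildEmissions:
    def test_no_data_is_uninformative(self):
        E = emission_child_mode({}, 0.3, _ped_child(), "e", PARAMS)
        assert np.ptp(E) == pytest.approx(0.0, abs=1e-15)

    def test_mendelian_forced_site_is_uninformative(self):
        # mother hom-alt, father hom-ref: child and embryo are het under
        # every state, so states cannot be distinguished
        counts = {"m": (0, 40), "f": (40, 0), "c": (18, 2), "e": (1, 1)}
        E = emission_child_mode(counts, 0.5, _ped_child(), "e", PARAMS)
        assert np.allclose(E, E[0], rtol=1e-12)

    def test_informative_site_favors_mismatch(self):
        params = ModelParams(eps=1e-6, ado=0.0)
        counts = {"m": (20, 20), "f": (40, 0), "c": (14, 0), "e": (0, 2)}
        E = emission_child_mode(counts, 0.5, _ped_child(), "e", params)
        maternal_match = E[0] + E[1]
        maternal_mismatch = E[2] + E[3]
        assert maternal_mismatch / maternal_match > 1e3

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        counts = {s: tuple(rng.integers(0, 8, 2)) for s in "mfce"}
        q = float(rng.uniform(0.05, 0.95))
        E = emission_child_mode(counts, q, _ped_child(), "e", PARAMS)
        oracle = child_emission_oracle(
            counts["m"], counts["f"], counts["c"], counts["e"], q, PARAMS.eps, PARAMS.ado
        )
        np.testing.assert_allclose(E, oracle, rtol=1e-9)


class TestGrandparentEmissions:
    def test_no_data_is_uninformative(self):
        E = emission_grandparent_mode({}, "maternal", 0.4, _ped_gp(), "e", PARAMS)
        assert E[0] == pytest.approx(E[1], rel=1e-12)

    def test_unphaseable_side_raises(self):
        with pytest.raises(ValueError, match="unphaseable|cannot be phased"):
            emission_grandparent_mode({}, "paternal", 0.4, _ped_gp(), "e", PARAMS)

    def test_informative_site_favors_carrier_grandparent(self):
        params = ModelParams(eps=1e-6, ado=0.0)
        counts = {"g1": (0, 40), "g2": (40, 0), "m": (20, 20), "f": (40, 0), "e": (0, 3)}
        E = emission_grandparent_mode(counts, "maternal", 0.5, _ped_gp(), "e", params)
        assert E[0] / E[1] > 1e3

    def test_single_grandparent_evidence_points_to_unsequenced_one(self):
        params = ModelParams(eps=1e-6, ado=0.0)
        counts = {"g1": (40, 0), "m": (20, 20), "f": (40, 0), "e": (0, 3)}
        E = emission_grandparent_mode(counts, "maternal", 0.5, _ped_gp(1), "e", params)
        assert E[1] > E[0]

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(500 + seed)
        n_gp = 1 + seed % 2
        samples = ["g1", "g2"][:n_gp] + ["m", "f", "e"]
        counts = {s: tuple(rng.integers(0, 8, 2)) for s in samples}
        q = float(rng.uniform(0.05, 0.95))
        E = emission_grandparent_mode(counts, "maternal", q, _ped_gp(n_gp), "e", PARAMS)
        oracle = grandparent_emission_oracle(
            counts.get("g1"), counts.get("g2"), counts["m"], counts["f"], counts["e"],
            q, PARAMS.eps, PARAMS.ado,
        )
        np.testing.assert_allclose(E, oracle, rtol=1e-9)


class TestRunPhasing:
    def test_one_track_per_embryo_per_side(self, child_family):
        table, pedigree, _ = child_family
        tracks = run_phasing(table, pedigree)
        assert len(tracks) == 2 * len(pedigree.embryos)
        for t in tracks:
            assert len(t.data) == table.n_sites
            assert np.all((t.marginal >= 0) & (t.marginal <= 1))
            passed = (t.marginal > PARAMS.conf_hi) | (t.marginal < PARAMS.conf_lo)
            assert np.array_equal(passed, t.passed)

    def test_embryo_identical_to_reference_child_matches_everywhere(self, child_family):
        table, pedigree, _ = child_family
        counts = dict(table.counts)
        counts["embryo1"] = table.counts_for("child").copy()
        tracks = run_phasing(SiteTable(table.sites, counts), pedigree)
        for t in tracks:
            if t.embryo != "embryo1":
                continue
            assert np.all(dichotomize(t.marginal[t.passed]))
            assert t.passed.mean() > 0.9

    def test_zero_coverage_embryo_gives_flat_marginals(self, child_family, caplog):
        table, pedigree, _ = child_family
        counts = dict(table.counts)
        counts["embryo1"] = np.zeros_like(table.counts_for("embryo1"))
        import logging

        with caplog.at_level(logging.WARNING):
            tracks = run_phasing(SiteTable(table.sites, counts), pedigree)
        assert any("no reads" in r.message for r in caplog.records)
        t = [t for t in tracks if t.embryo == "embryo1"][0]
        assert np.all(np.abs(t.marginal - 0.5) < 0.5 - PARAMS.conf_lo)
        assert not t.passed.any()

    def test_grandparent_label_swap_mirrors_marginals(self, gp_family):
        table, pedigree, _ = gp_family
        swapped = Pedigree(
            mother_id=pedigree.mother_id, father_id=pedigree.father_id,
            embryos=pedigree.embryos, reference_mode="grandparent",
            grandparents={
                "maternal": list(reversed(pedigree.grandparents["maternal"])),
                "paternal": pedigree.grandparents["paternal"],
            },
            sex=pedigree.sex,
        )
        t1 = run_phasing(table, pedigree)
        t2 = run_phasing(table, swapped)
        a = [t for t in t1 if t.side == "maternal"][0]
        b = [t for t in t2 if t.side == "maternal"][0]
        np.testing.assert_allclose(b.marginal, 1.0 - a.marginal, atol=1e-9)

    def test_joint_chain_marginalises_to_two_state_when_father_homozygous(self):
        """With the father homozygous everywhere the paternal side is
        uninformative and the 4-state chain must reduce to the maternal
        2-state chain exactly."""
        rng = np.random.default_rng(11)
        n = 400
        pos = np.sort(rng.choice(20_000_000, n, replace=False)) + 1
        q = rng.uniform(0.2, 0.8, n)
        sites = pd.DataFrame(
            {"chrom": "chr1", "pos": pos, "ref": "A", "alt": "C", "alt_freq": q}
        )
        hm = (rng.random((2, n)) < q).astype(int)
        counts = {
            "m": np.stack([(hm.sum(0) == 0) * 4 + (hm.sum(0) == 1) * 2,
                           (hm.sum(0) == 2) * 4 + (hm.sum(0) == 1) * 2], 1),
            "f": np.stack([np.full(n, 400), np.zeros(n, int)], 1),  # certainly hom ref
            "c": np.stack([(1 - hm[0]) * 3, hm[0] * 3], 1),
            "e": np.stack([(1 - hm[0]) * (rng.random(n) < 0.3), hm[0] * (rng.random(n) < 0.3)], 1).astype(int),
        }
        table = SiteTable(sites, counts)
        ped = _ped_child()
        tracks = run_phasing(table, ped)
        maternal = [t for t in tracks if t.side == "maternal"][0]

        prior = genotype_prior_table(q)
        E4 = child_emissions(
            read_likelihood_table(counts["m"], PARAMS.eps),
            read_likelihood_table(counts["f"], PARAMS.eps),
            read_likelihood_table(counts["c"], PARAMS.eps),
            embryo_read_likelihood_table(counts["e"], PARAMS.eps, PARAMS.ado),
            prior,
        )
        np.testing.assert_allclose(E4[:, 0], E4[:, 1], rtol=1e-10)
        r = switch_probs(pos, PARAMS, 2)
        post2, _ = hmm.forward_backward(E4[:, [0, 2]], _two_state_stack(r))
        np.testing.assert_allclose(maternal.marginal, post2[:, 0], atol=1e-9)

    def test_chrx_present_only_in_maternal_tracks(self):
        from famphase.simulate import SimConfig, simulate_family

        sim = simulate_family(
            SimConfig(chrom_lengths={"chr1": 20_000_000}, n_sites_per_chrom=800,
                      include_chrx=True, chrx_length=20_000_000,
                      embryo_sexes=["female", "male", "female"], seed=4)
        )
        tracks = run_phasing(sim.table, sim.pedigree)
        for t in tracks:
            n_x = (t.data["chrom"] == "chrX").sum()
            assert (n_x > 0) == (t.side == "maternal")

    def test_accuracy_does_not_degrade_with_parental_depth(self):
        """Median pass-site concordance is non-decreasing from 1x to 4x."""
        from famphase.simulate import SimConfig, simulate_family

        medians = []
        for depth in (1.0, 2.0, 4.0):
            concs = []
            for seed in (31, 32, 33):
                sim = simulate_family(
                    SimConfig(chrom_lengths={"chr1": 30_000_000, "chr2": 30_000_000},
                              n_sites_per_chrom=2500, n_embryos=2,
                              depth_mother=depth, depth_father=depth,
                              depth_reference=depth, seed=seed)
                )
                rep = evaluate_family(run_phasing(sim.table, sim.pedigree), sim.truth)
                concs.extend(rep.concordance.dropna().tolist())
            medians.append(np.median(concs))
        assert medians[0] <= medians[1] + 1e-12
        assert medians[1] <= medians[2] + 1e-12


class TestModelResults:
    def test_fit_returns_summary_per_track(self, child_family):
        table, pedigree, _ = child_family
        res = FamilyPhasingModel(table, pedigree).fit(filter_sites=False)
        summ = res.summary()
        assert len(summ) == 2 * len(pedigree.embryos)
        assert set(summ.columns) >= {"embryo", "side", "n_sites", "prop_pass"}
        track = res.track("embryo1", "maternal")
        assert track.side == "maternal"

    def test_results_round_trip_via_tsv(self, child_family, tmp_path):
        from famphase.io import load_track_tsv

        table, pedigree, _ = child_family
        res = FamilyPhasingModel(table, pedigree).fit(filter_sites=False)
        res.to_dir(tmp_path)
        t = res.tracks[0]
        again = load_track_tsv(tmp_path / f"track_{t.embryo}_{t.side}.tsv")
        assert again.embryo == t.embryo and again.side == t.side
        np.testing.assert_allclose(again.marginal, t.marginal, atol=5e-7)
        assert np.array_equal(again.prediction, t.prediction)
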