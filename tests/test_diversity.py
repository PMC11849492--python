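"""Diversity metrics, PERMANOVA, and species/diversity-SIP associations."""

import numpy as np
import pandas as pd
import pytest

from dermalink import diversity
from dermalink.diversity import DistanceMatrix
from dermalink.simulate import SIP_COLUMNS


def _profile(columns: dict) -> pd.DataFrame:
    return pd.DataFrame(columns)


class TestShannon:
    def test_uniform_profile_is_log_richness(self):
        prof = _profile({"s1": [1.0, 1.0, 1.0, 1.0]})
        assert diversity.shannon(prof)["s1"] == pytest.approx(np.log(4), abs=1e-9)

    def test_single_taxon_zero(self):
        prof = _profile({"s1": [5.0, 0.0, 0.0]})
        assert diversity.shannon(prof)["s1"] == pytest.approx(0.0, abs=1e-12)

    def test_known_mixture(self):
        prof = _profile({"s1": [0.5, 0.25, 0.25]})
        assert diversity.shannon(prof)["s1"] == pytest.approx(1.039721, abs=1e-6)

    def test_all_zero_sample_named(self):
        prof = _profile({"good": [1.0, 1.0], "bad": [0.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            diversity.shannon(prof)

    def test_matches_textbook_formula_on_random_profiles(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(2, 30))
            prof = _profile({"s": p})
            rel = p / p.sum()
            expected = -sum(q * np.log(q) for q in rel if q > 0)
            assert diversity.shannon(prof)["s"] == pytest.approx(expected, abs=1e-9)


class TestBrayCurtis:
    def test_identical_samples_distance_zero(self):
        prof = _profile({"a": [0.3, 0.7], "b": [0.3, 0.7]})
        assert diversity.bray_curtis(prof).values[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_distance_one(self):
        prof = _profile({"a": [1.0, 0.0], "b": [0.0, 1.0]})
        assert diversity.bray_curtis(prof).values[0, 1] == pytest.approx(1.0)

    def test_known_pair(self):
        prof = _profile({"a": [0.6, 0.4], "b": [0.2, 0.8]})
        assert diversity.bray_curtis(prof).values[0, 1] == pytest.approx(0.4, abs=1e-9)

    def test_matches_textbook_formula_on_random_profiles(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.random(10)
            y = rng.random(10)
            prof = _profile({"a": x, "b": y})
            xr, yr = x / x.sum(), y / y.sum()
            expected = np.abs(xr - yr).sum() / (xr + yr).sum()
            assert diversity.bray_curtis(prof).values[0, 1] == pytest.approx(
                expected, abs=1e-9
            )


@pytest.fixture
def two_cluster_distance():
    d = np.array(
        [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0], [1, 1, 0, 0]], dtype=float
    )
    return DistanceMatrix(ids=list("abcd"), values=d)


class TestPermanova:
    def test_two_cluster_fixture_r2_one_enumeration_p(self, two_cluster_distance):
        res = diversity.permanova(
            two_cluster_distance,
            pd.Series(["g1", "g1", "g2", "g2"]),
            n_permutations="exhaustive",
        )
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_constant_variable_rejected(self, two_cluster_distance):
        with pytest.raises(ValueError, match="zero design variance"):
            diversity.permanova(two_cluster_distance, pd.Series(["g"] * 4))

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0, 1.0], [0.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], values=bad)

    def test_statistic_invariant_to_joint_relabeling(self, two_cluster_distance):
        var = pd.Series(["g1", "g1", "g2", "g2"])
        base = diversity.permanova(two_cluster_distance, var, n_permutations="exhaustive")
        perm = np.array([2, 0, 3, 1])
        shuffled = DistanceMatrix(
            ids=[two_cluster_distance.ids[i] for i in perm],
            values=two_cluster_distance.values[np.ix_(perm, perm)],
        )
        res = diversity.permanova(
            shuffled, var.iloc[perm].reset_index(drop=True), n_permutations="exhaustive"
        )
        assert res.r2 == pytest.approx(base.r2, abs=1e-12)
        assert res.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_duplicating_samples_preserves_r2(self, two_cluster_distance):
        var = pd.Series(["g1", "g1", "g2", "g2"])
        base = diversity.permanova(two_cluster_distance, var, n_permutations=9, seed=0)
        big = np.kron(np.ones((2, 2)), two_cluster_distance.values)
        np.fill_diagonal(big, 0.0)
        idx = [0, 1, 2, 3, 0, 1, 2, 3]
        dup = DistanceMatrix(ids=[f"x{i}" for i in range(8)], values=big[np.ix_(idx, idx)])
        res = diversity.permanova(dup, pd.concat([var, var], ignore_index=True), 9, 0)
        assert res.r2 == pytest.approx(base.r2, abs=1e-9)

    def test_two_level_factor_r2_matches_closed_form(self):
        # R^2 = 1 - SSW/SST, with sums of squared distances within groups
        rng = np.random.default_rng(2)
        prof = pd.DataFrame(rng.random((12, 10)), columns=[f"s{i}" for i in range(10)])
        dist = diversity.bray_curtis(prof)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        d2 = dist.values**2
        n = 10
        sst = d2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in ("a", "b"):
            idx = np.flatnonzero(labels == g)
            ssw += d2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        res = diversity.permanova(dist, pd.Series(labels), n_permutations=9, seed=0)
        assert res.r2 == pytest.approx(1 - ssw / sst, abs=1e-9)

    def test_pseudo_f_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        prof = pd.DataFrame(rng.random((15, 20)), columns=[f"s{i}" for i in range(20)])
        dist = diversity.bray_curtis(prof)
        labels = ["a"] * 7 + ["b"] * 7 + ["c"] * 6
        ours = diversity.permanova(dist, pd.Series(labels), n_permutations=99, seed=0)
        ref = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(dist.values, ids=dist.ids), grouping=labels, permutations=99
        )
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]), rel=1e-9)

    def test_null_type_one_error_rate(self):
        hits = 0
        reps = 200
        for i in range(reps):
            rng = np.random.default_rng(500 + i)
            prof = pd.DataFrame(
                rng.dirichlet(np.ones(20), 60).T, columns=[f"s{j}" for j in range(60)]
            )
            dist = diversity.bray_curtis(prof)
            res = diversity.permanova(
                dist, pd.Series(rng.standard_normal(60)), n_permutations=299, seed=i
            )
            hits += res.p_value < 0.05
        assert 0.02 <= hits / reps <= 0.08


class TestPermanovaCombined:
    def test_null_total_r2_near_expectation(self):
        # independent noise: E[R^2] ~ q / (n - 1)
        n, q = 200, 11
        ratios = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            prof = pd.DataFrame(
                rng.dirichlet(np.ones(30), n).T, columns=[f"s{j}" for j in range(n)]
            )
            dist = diversity.bray_curtis(prof)
            variables = pd.DataFrame(
                rng.standard_normal((n, q)), columns=[f"v{j}" for j in range(q)]
            )
            total, _ = diversity.permanova_combined(dist, variables, n_permutations=0)
            ratios.append(total.r2 / (q / (n - 1)))
        assert 0.5 <= np.mean(ratios) <= 1.5

    def test_single_explaining_variable_dominates(self, two_cluster_distance):
        variables = pd.DataFrame(
            {"group": [0.0, 0.0, 1.0, 1.0], "noise": [0.1, 0.9, 0.5, 0.3]}
        )
        total, marginals = diversity.permanova_combined(
            two_cluster_distance, variables, n_permutations=0
        )
        group_marginal = next(m for m in marginals if m.variable == "group")
        assert total.r2 == pytest.approx(1.0, abs=1e-9)
        assert group_marginal.r2 == pytest.approx(1.0, abs=1e-9)

    def test_duplicate_column_rejected(self, two_cluster_distance):
        variables = pd.DataFrame(
            {"a": [0.0, 1.0, 2.0, 3.0], "b": [0.0, 1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="collinear.*b"):
            diversity.permanova_combined(two_cluster_distance, variables, 0)


class TestDiversitySipAssociations:
    def test_age_rho_for_monotone_diversity(self, default_study, ages_of):
        # near-monotone in age (exact monotonicity would make the
        # age-adjusted SIP correlations degenerate by construction)
        rng = np.random.default_rng(6)
        ages = ages_of(default_study)
        div = pd.Series(
            np.asarray(ages) * 2 + 1 + rng.normal(0, 0.3, len(ages)), index=ages.index
        )
        res = diversity.diversity_sip_associations(div, default_study.phenome, ages)
        by_var = res.set_index("variable")
        assert by_var.loc["age", "rho"] > 0.99
        assert (by_var.drop("age")["q_value"] > 0.1).sum() >= 8

    def test_constructed_sip_coupling_recovered(self, default_study, ages_of):
        rng = np.random.default_rng(4)
        ages = ages_of(default_study)
        pore = default_study.phenome["pore"].to_numpy()
        div = pore + rng.normal(0, pore.std() * 0.5, len(pore))
        res = diversity.diversity_sip_associations(
            pd.Series(div, index=ages.index), default_study.phenome, ages
        ).set_index("variable")
        assert res.loc["pore", "q_value"] < 0.1
        assert res.loc["pore", "rho"] > 0

    def test_too_few_samples_rejected(self, default_study):
        small = default_study.phenome.iloc[:2]
        with pytest.raises(ValueError):
            diversity.diversity_sip_associations(
                pd.Series([1.0, 2.0], index=small.index), small, [30.0, 40.0]
            )


class TestSpeciesSipAssociation:
    def test_planted_driver_association_recovered(self, driver_study, ages_of):
        ages = ages_of(driver_study)
        res = diversity.species_sip_association(
            driver_study.species, driver_study.phenome, ages
        )
        truth = driver_study.truth
        row = res[(res.species == truth.driver_species_id) & (res.sip == truth.target_sip)]
        assert len(row) == 1
        assert row["coefficient"].iloc[0] < 0  # planted correlation is negative
        assert row["q_value"].iloc[0] < 0.1

    def test_null_false_discovery_controlled(self, default_study, ages_of):
        rng = np.random.default_rng(5)
        ages = ages_of(default_study)
        shuffled = default_study.species.sample(
            frac=1.0, axis=1, random_state=7
        )
        shuffled.columns = default_study.species.columns
        res = diversity.species_sip_association(shuffled, default_study.phenome, ages)
        assert (res["q_value"] < 0.1).mean() <= 0.1

    def test_absent_species_filtered(self, default_study, ages_of):
        species = default_study.species.copy()
        species.iloc[0] = 0.0
        res = diversity.species_sip_association(
            species, default_study.phenome, ages_of(default_study)
        )
        assert species.index[0] not in set(res["species"])
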