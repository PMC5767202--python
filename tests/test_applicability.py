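import numpy as np
import pytest

from lieflow import SyntheticSpec, assess, build_ad_reference, calibrate_iterative, tanimoto
from lieflow.applicability import (
    ADQuery,
    criterion1_range,
    criterion2_similarity,
    criterion3_energy,
    criterion45_decomposition,
    fit_pca_reference,
    mahalanobis_distance,
    most_central_member,
    query_from_training_compound,
)
from lieflow.synthetic import generate_training_set, out_of_domain_query


def bitvec(on_bits, length=8):
    v = np.zeros(length, dtype=bool)
    v[list(on_bits)] = True
    return v


class TestTanimoto:
    def test_identity_and_disjoint(self):
        a = bitvec({1, 2, 3})
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, bitvec({4, 5})) == 0.0

    def test_hand_value(self):
        assert tanimoto(bitvec({1, 2, 3}), bitvec({1, 2, 4})) == pytest.approx(0.5)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            tanimoto(bitvec(set()), bitvec(set()))

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(bitvec({1}, 8), bitvec({1}, 16))


@pytest.fixture(scope="module")
def trained():
    training = generate_training_set(SyntheticSpec(n_compounds=20, seed=21))
    params = calibrate_iterative(training).parameters
    reference = build_ad_reference(training, params)
    return training, params, reference


class TestBuildReference:
    def test_tanimoto_cutoff_hand_enumeration(self, trained):
        # A={1,2,3}, B={1,2,4}, C={1,5,6}: pairwise TS 0.5/0.2/0.2,
        # per-compound best (0.5, 0.5, 0.2) -> cutoff 0.2
        fps = [bitvec({1, 2, 3}), bitvec({1, 2, 4}), bitvec({1, 5, 6})]
        best = [
            max(tanimoto(fps[i], fps[j]) for j in range(3) if j != i) for i in range(3)
        ]
        assert best == pytest.approx([0.5, 0.5, 0.2])
        assert min(best) == pytest.approx(0.2)
        # same quantity through the reference builder on a synthetic set
        training, params, reference = trained
        from lieflow.applicability import ADReference  # sanity of frozen stats

        nn = [
            max(
                tanimoto(training[i].fingerprint, training[j].fingerprint)
                for j in range(len(training))
                if j != i
            )
            for i in range(len(training))
        ]
        assert reference.ts_cutoff == pytest.approx(min(nn))

    def test_dg_range_covers_calculated_training_values(self, trained):
        training, params, reference = trained
        from lieflow import predict

        dg = [predict(params, c.energetics).dg_pred for c in training]
        assert reference.dg_range == pytest.approx((min(dg), max(dg)))

    def test_missing_annotations_listed(self, trained):
        training, params, _ = trained
        import dataclasses

        broken = [dataclasses.replace(training[0], fingerprint=None)] + list(training[1:])
        with pytest.raises(ValueError, match=training[0].compound_id):
            build_ad_reference(broken, params)

    def test_permuting_training_list_changes_nothing(self, trained):
        training, params, reference = trained
        permuted = build_ad_reference(training[::-1], params)
        assert permuted.ts_cutoff == pytest.approx(reference.ts_cutoff)
        assert permuted.dg_range == pytest.approx(reference.dg_range)
        assert permuted.mahalanobis_threshold == pytest.approx(reference.mahalanobis_threshold)
        q = query_from_training_compound(training[3], params)
        assert assess(q, permuted).flags == assess(q, reference).flags


class TestCriteria:
    def test_range_criterion_boundaries(self, trained):
        _, _, ref = trained
        lo, hi = ref.dg_range
        assert criterion1_range((lo + hi) / 2, ref) == 0
        assert criterion1_range(lo, ref) == 0  # inclusive at the boundary
        assert criterion1_range(hi, ref) == 0
        assert criterion1_range(lo - 0.1, ref) == 1
        assert criterion1_range(hi + 0.1, ref) == 1

    def test_similarity_criterion_is_strict_at_cutoff(self, trained):
        training, _, ref = trained
        assert criterion2_similarity(training[0].fingerprint, ref) == 0  # identical member
        novel = np.zeros(ref.fingerprints.shape[1], dtype=bool)
        novel[np.flatnonzero(~ref.fingerprints.any(axis=0))[:4]] = True
        assert criterion2_similarity(novel, ref) == 1  # disjoint from all

    def test_similarity_exactly_at_cutoff_violates(self):
        # best TS == cutoff must flag, per the strict "higher than" rule
        from lieflow.applicability import ADReference, PCAReference

        fps = np.array(
            [bitvec({1, 2, 3}, 16), bitvec({1, 2, 4}, 16), bitvec({1, 5, 6}, 16)]
        )
        pca = PCAReference(
            mean=np.zeros(2), components=np.eye(2), eigenvalues=np.ones(2),
            sd_threshold=1.0, od_threshold=1.0,
        )
        ref = ADReference(
            dg_range=(-50.0, -30.0), ts_cutoff=0.2, fingerprints=fps,
            energy_centroid=np.zeros(2), energy_covariance=np.eye(2),
            mahalanobis_threshold=1.0, pca_vdw=pca, pca_ele=pca,
        )
        query = bitvec({1, 9, 10}, 16)  # one shared bit, union 5 vs every member
        best = max(tanimoto(query, fp) for fp in fps)
        assert best == pytest.approx(0.2)
        assert criterion2_similarity(query, ref) == 1

    def test_energy_criterion_distances(self, trained):
        _, _, ref = trained
        assert criterion3_energy(ref.energy_centroid, ref) == 0  # distance zero
        evals, evecs = np.linalg.eigh(ref.energy_covariance)
        far = ref.energy_centroid + 10 * ref.mahalanobis_threshold * np.sqrt(evals[-1]) * evecs[:, -1]
        assert criterion3_energy(far, ref) == 1

    def test_mahalanobis_identity_covariance_is_euclidean(self):
        d = mahalanobis_distance(np.array([3.0, 4.0]), np.zeros(2), np.eye(2))
        assert d == pytest.approx(5.0)

    def test_decomposition_orthogonal_escape(self, trained):
        _, _, ref = trained
        pca = ref.pca_vdw
        assert criterion45_decomposition(pca.mean, pca) == 0  # score distance 0
        v = np.random.default_rng(3).normal(size=pca.mean.size)
        v -= pca.components.T @ (pca.components @ v)
        v *= 100 * max(pca.od_threshold, 1.0) / np.linalg.norm(v)
        sd, od = pca.distances(pca.mean + v)
        assert sd == pytest.approx(0.0, abs=1e-8)
        assert od > pca.od_threshold
        assert criterion45_decomposition(pca.mean + v, pca) == 1

    def test_empirical_percentile_flag_rate(self):
        """Criterion 3 fit on its own training set flags ~5% of it."""
        rng = np.random.default_rng(12)
        cov = np.array([[144.0, 30.0], [30.0, 64.0]])
        X = rng.multivariate_normal([-60.0, -25.0], cov, size=2000)
        centroid = X.mean(axis=0)
        S = np.cov(X, rowvar=False)
        d = np.array([mahalanobis_distance(x, centroid, S) for x in X])
        threshold = np.percentile(d, 95.0)
        inside = np.mean(d <= threshold)
        assert inside == pytest.approx(0.95, abs=0.005)


class TestConfidenceIndex:
    def test_extremes_and_summation(self, trained):
        training, params, ref = trained
        spec = SyntheticSpec(n_compounds=20, seed=21)
        ood = out_of_domain_query(ref, spec)
        report = assess(ood, ref)
        assert report.ci_total == 5
        assert all(v == 1 for v in report.flags.values())

        central = most_central_member(training, ref, params)
        report0 = assess(central, ref)
        assert report0.ci_total == 0
        assert all(v == 0 for v in report0.flags.values())

    def test_each_criterion_triggers_independently(self, trained):
        training, params, ref = trained
        spec = SyntheticSpec(n_compounds=20, seed=21)
        base = most_central_member(training, ref, params)
        ood = out_of_domain_query(ref, spec)
        single_field = {
            "c1": {"dg_pred": ood.dg_pred},
            "c2": {"fingerprint": ood.fingerprint},
            "c3": {"energy_pair": ood.energy_pair},
            "c4": {"decomposition_vdw": ood.decomposition_vdw},
            "c5": {"decomposition_ele": ood.decomposition_ele},
        }
        import dataclasses

        for criterion, patch in single_field.items():
            query = dataclasses.replace(base, **patch)
            report = assess(query, ref)
            assert report.flags[criterion] == 1
            assert report.ci_total == 1, f"{criterion} should be the only violation"

    def test_ci_total_is_flag_sum(self, trained):
        training, params, ref = trained
        for compound in training[:5]:
            report = assess(query_from_training_compound(compound, params), ref)
            assert report.ci_total == sum(report.flags.values())
            assert 0 <= report.ci_total <= 5


class TestPcaRetention:
    def test_five_percent_rule_on_constructed_spectrum(self):
        # exact variance fractions (0.60, 0.25, 0.10, 0.04, 0.01) -> 3 retained
        rng = np.random.default_rng(0)
        n, p = 200, 12
        fractions = np.array([0.60, 0.25, 0.10, 0.04, 0.01])
        basis, _ = np.linalg.qr(rng.normal(size=(p, 5)))
        scores = rng.normal(size=(n, 5))
        scores -= scores.mean(axis=0)
        scores, _ = np.linalg.qr(scores)  # orthonormal columns
        scores *= np.sqrt(fractions * (n - 1))
        X = scores @ basis.T
        ref = fit_pca_reference(X)
        assert ref.components.shape[0] == 3

    def test_rank_one_data_retains_one_component(self):
        rng = np.random.default_rng(1)
        totals = rng.normal(-60, 12, 40)
        base = rng.dirichlet(np.full(10, 2.0))
        X = np.outer(totals, base)
        ref = fit_pca_reference(X)
        assert ref.components.shape[0] == 1
        sd, od = ref.distances(X[0])
        assert od == pytest.approx(0.0, abs=1e-8)
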