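import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffpefilter import (
    DEFAULT_SCHEMA,
    SUBSTITUTION_TYPES,
    FeatureSchema,
    VariantCall,
    VariantKey,
    apply_scaler,
    build_feature_vector,
    classify_substitution,
    compute_maf,
    compute_orientation_cosine,
    compute_sob,
    featurize_calls,
    fit_scaler,
)

counts = st.integers(min_value=0, max_value=10_000)


def make_call(ref="C", alt="T", **kw):
    defaults = dict(depth=100, ad_ref=90, ad_alt=10, f1r2_ref=45, f1r2_alt=8,
                    f2r1_ref=45, f2r1_alt=2, mbq_ref=32.0, mbq_alt=30.0,
                    mmq_ref=60.0, mmq_alt=60.0, mfrl_ref=220.0, mfrl_alt=150.0,
                    mpos=20.0, tlod=30.5, ecnt=1, popaf=6.0, germq=90.0,
                    seqq=80.0, strandq=30.0, roq=40.0)
    defaults.update(kw)
    return VariantCall(VariantKey("chr1", 100, ref, alt), **defaults)


class TestMaf:
    @pytest.mark.parametrize("ad_ref,ad_alt,expected", [
        (90, 10, 0.10),
        (0, 25, 1.0),
        (343, 45, 0.1160),  # 45/388
    ])
    def test_hand_values(self, ad_ref, ad_alt, expected):
        c = make_call(ad_ref=ad_ref, ad_alt=ad_alt)
        assert compute_maf(c) == pytest.approx(expected, abs=5e-5)

    def test_zero_depth_sum_is_an_error(self):
        with pytest.raises(ValueError):
            compute_maf(make_call(ad_ref=0, ad_alt=0))


class TestSob:
    @pytest.mark.parametrize("f1, f2, expected", [
        (10, 10, 0.0),
        (10, 0, 1.0),
        (0, 10, 1.0),
        (15, 5, 0.5),
    ])
    def test_hand_values(self, f1, f2, expected):
        assert compute_sob(f1, f2) == pytest.approx(expected)

    def test_no_support_is_missing(self):
        assert math.isnan(compute_sob(0, 0))

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            compute_sob(-1, 5)

    @settings(derandomize=True, max_examples=200)
    @given(a=counts, b=counts)
    def test_symmetric_and_bounded(self, a, b):
        if a + b == 0:
            assert math.isnan(compute_sob(a, b))
        else:
            s = compute_sob(a, b)
            assert s == compute_sob(b, a)
            assert 0.0 <= s <= 1.0


class TestOrientationCosine:
    def test_parallel_vectors(self):
        assert compute_orientation_cosine((50, 50), (25, 25)) == pytest.approx(1.0)

    def test_hand_value(self):
        # 500 / (sqrt(5000) * 10)
        assert compute_orientation_cosine((50, 50), (10, 0)) == pytest.approx(0.7071, abs=5e-5)

    def test_zero_vector_is_missing(self):
        assert math.isnan(compute_orientation_cosine((0, 0), (5, 5)))
        assert math.isnan(compute_orientation_cosine((5, 5), (0, 0)))

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            compute_orientation_cosine((-1, 1), (1, 1))

    @settings(derandomize=True, max_examples=100)
    @given(a=counts.filter(lambda x: x > 0), b=counts, k=st.integers(1, 50))
    def test_invariant_to_positive_scaling(self, a, b, k):
        base = compute_orientation_cosine((a, b), (3, 7))
        scaled = compute_orientation_cosine((k * a, k * b), (3, 7))
        assert scaled == pytest.approx(base, abs=1e-9)


class TestClassifySubstitution:
    def test_direct_and_length_rules(self):
        assert classify_substitution("C", "T") == "C>T"
        assert classify_substitution("A", "AT") == "INS"
        assert classify_substitution("AT", "A") == "DEL"
        assert classify_substitution("AT", "GC") == "COMPLEX"

    def test_enumeration_gives_twelve_distinct_labels(self):
        labels = {
            classify_substitution(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        }
        assert labels == set(SUBSTITUTION_TYPES)
        assert len(labels) == 12

    def test_non_acgt_raises(self):
        with pytest.raises(ValueError):
            classify_substitution("N", "T")


class TestBuildFeatureVector:
    def test_vector_has_41_entries(self):
        fv = build_feature_vector(make_call())
        assert fv.values.shape == (41,)
        assert len(DEFAULT_SCHEMA) == 41

    def test_snv_onehot_blocks(self):
        fv = build_feature_vector(make_call("C", "T"))
        names = DEFAULT_SCHEMA.names
        vclass = [fv.values[names.index(n)] for n in ("is_SNV", "is_INS", "is_DEL")]
        assert vclass == [1.0, 0.0, 0.0]
        subs = [fv.values[i] for i, n in enumerate(names) if n.startswith("sub_")]
        assert sum(subs) == 1.0
        assert fv.values[names.index("sub_C_T")] == 1.0

    def test_indel_and_complex_onehot(self):
        ins = build_feature_vector(make_call("A", "AT"))
        names = DEFAULT_SCHEMA.names
        assert ins.values[names.index("is_INS")] == 1.0
        assert sum(ins.values[i] for i, n in enumerate(names) if n.startswith("sub_")) == 0.0
        mnv = build_feature_vector(make_call("AT", "GC"))
        # variant-class block still sums to 1; substitution flags stay zero
        assert sum(mnv.values[names.index(n)] for n in ("is_SNV", "is_INS", "is_DEL")) == 1.0
        assert sum(mnv.values[i] for i, n in enumerate(names) if n.startswith("sub_")) == 0.0

    def test_missing_annotation_flagged_for_imputation(self):
        fv = build_feature_vector(make_call(mmq_ref=None, mmq_alt=None))
        idx = DEFAULT_SCHEMA.names.index("MMQ_ref")
        assert math.isnan(fv.values[idx]) and fv.imputed[idx]
        assert not fv.imputed[DEFAULT_SCHEMA.names.index("DP")]

    def test_pure_function_of_call(self):
        a = build_feature_vector(make_call())
        b = build_feature_vector(make_call())
        np.testing.assert_array_equal(a.values, b.values)

    def test_wrong_schema_length_raises(self):
        with pytest.raises(ValueError):
            build_feature_vector(make_call(), FeatureSchema(names=("a", "b"), version="bad"))


class TestScaler:
    def test_zscore_with_known_moments(self):
        schema = DEFAULT_SCHEMA
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 2.0, size=(400, 41))
        X[:, schema.onehot_mask] = 0.0
        sc = fit_scaler(X)
        i = schema.names.index("DP")
        v = X[0].copy()
        v[i] = X[:, i].mean() + 2 * X[:, i].std()
        assert apply_scaler(sc, v)[i] == pytest.approx(2.0)

    def test_train_matrix_maps_to_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2.0, 3.0, size=(500, 41))
        sc = fit_scaler(X)
        Z = apply_scaler(sc, X)
        num = ~DEFAULT_SCHEMA.onehot_mask
        np.testing.assert_allclose(Z[:, num].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z[:, num].std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        X = np.ones((50, 41)) * 7.0
        Z = apply_scaler(fit_scaler(X), X)
        assert np.allclose(Z[:, ~DEFAULT_SCHEMA.onehot_mask], 0.0)

    def test_missing_values_imputed_with_train_median(self):
        X = np.ones((11, 41)) * 4.0
        i = DEFAULT_SCHEMA.names.index("MMQ_ref")
        X[:, i] = np.arange(11, dtype=float)  # median 5
        v = np.full(41, 4.0)
        v[i] = np.nan
        z = apply_scaler(fit_scaler(X), v)
        med_z = (5.0 - X[:, i].mean()) / X[:, i].std()
        assert z[i] == pytest.approx(med_z)

    def test_empty_training_set_raises(self):
        with pytest.raises(ValueError):
            fit_scaler(np.empty((0, 41)))

    def test_onehot_passthrough(self):
        rng = np.random.default_rng(2)
        X = rng.random((100, 41))
        X[:, DEFAULT_SCHEMA.onehot_mask] = rng.integers(0, 2, (100, int(DEFAULT_SCHEMA.onehot_mask.sum())))
        Z = apply_scaler(fit_scaler(X), X)
        np.testing.assert_array_equal(Z[:, DEFAULT_SCHEMA.onehot_mask], X[:, DEFAULT_SCHEMA.onehot_mask])


def test_class_separation_directions_recovered():
    """On artifact-enriched synthetic data the documented directions hold:
    artifact MAF is lower, artifact SOB is higher."""
    from ffpefilter import SyntheticConfig, generate_paired_dataset, label_ffpe_calls, Label
    from ffpefilter.features import compute_maf, compute_sob

    ff, ffpe, _ = generate_paired_dataset(SyntheticConfig(seed=5))
    labeled = label_ffpe_calls(ffpe, ff)
    maf = {Label.TRUE_VARIANT: [], Label.FFPE_ARTIFACT: []}
    sob = {Label.TRUE_VARIANT: [], Label.FFPE_ARTIFACT: []}
    for lv in labeled:
        maf[lv.label].append(compute_maf(lv.call))
        sob[lv.label].append(compute_sob(lv.call.f1r2_alt, lv.call.f2r1_alt))
    assert np.median(maf[Label.FFPE_ARTIFACT]) < np.median(maf[Label.TRUE_VARIANT])
    assert np.median(sob[Label.FFPE_ARTIFACT]) > np.median(sob[Label.TRUE_VARIANT])
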