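"""Mutation counting, one-control reactivity, depth/rate thresholds and
profile PCA."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xcikit.shape import (
    PositionProfile,
    count_mutations,
    merge_amplicons,
    pca_profiles,
    positive_calls,
    profiled_positions,
    reactivity,
)
from xcikit.synthetic import gen_shape_profiles, write_profile_sam


def make_read(ref_start, cigar, name="r"):
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "transcript", "LN": 10000}]}
    )
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_id = 0
    a.reference_start = ref_start
    a.cigarstring = cigar
    a.flag = 0
    a.mapping_quality = 60
    return a


def profile_of(depth, events, min_depth=0):
    return PositionProfile(
        depth=np.asarray(depth), mutation_events=np.asarray(events), min_depth=min_depth
    )


# ---------------------------------------------------------------------------
# count_mutations


def test_clean_read_counts_depth_only():
    read = make_read(0, "100=")
    prof = count_mutations([read], 100, primer_length=10, min_depth=0)
    assert prof.mutation_events.sum() == 0
    assert (prof.depth[10:90] == 1).all()
    assert (prof.depth[:10] == 0).all() and (prof.depth[90:] == 0).all()


def test_mismatch_inside_trimmed_end_not_counted():
    # mismatch at aligned position 5 (< primer_length) must vanish
    read = make_read(0, "5=1X94=")
    prof = count_mutations([read], 100, primer_length=30, min_depth=0)
    assert prof.mutation_events.sum() == 0


def test_mismatch_in_kept_interior_counted():
    read = make_read(0, "50=1X49=")
    prof = count_mutations([read], 100, primer_length=30, min_depth=0)
    assert prof.mutation_events[50] == 1
    assert prof.mutation_events.sum() == 1


def test_deletion_counts_one_event_per_reference_position():
    read = make_read(0, "50=2D48=")
    prof = count_mutations([read], 100, primer_length=10, min_depth=0)
    assert prof.mutation_events[50] == 1 and prof.mutation_events[51] == 1
    assert prof.depth[50] == 1 and prof.depth[51] == 1


def test_insertion_assigned_to_preceding_position():
    read = make_read(0, "50=3I50=")
    prof = count_mutations([read], 100, primer_length=10, min_depth=0)
    assert prof.mutation_events[49] == 1
    assert prof.mutation_events.sum() == 1


def test_trim_one_end_only_when_flag_off():
    read = make_read(0, "5=1X93=1X")  # mismatches at positions 5 and 99
    prof = count_mutations([read], 100, primer_length=30, trim_both_ends=False,
                           min_depth=0)
    assert prof.mutation_events[5] == 1  # left end kept
    assert prof.mutation_events[99] == 0  # right (primer) end trimmed


def test_unmapped_records_skipped_but_all_bad_errors():
    bad = make_read(0, "50=")
    bad.is_unmapped = True
    with pytest.raises(ValueError, match="no usable"):
        count_mutations([bad], 100, min_depth=0)
    ok = make_read(0, "100=")
    prof = count_mutations([bad, ok], 100, primer_length=10, min_depth=0)
    assert prof.depth.sum() == 80


def test_sam_round_trip_reproduces_generator_counts(tmp_path):
    profiles, truth = gen_shape_profiles(
        seq_length=120, true_reactivity=0.01, background_rate=0.005,
        depth=150, samples=("treated",), seed=9, min_depth=0,
    )
    prof = profiles[0]
    sam = tmp_path / "treated.sam"
    padded = write_profile_sam(prof, str(sam), primer_length=30, seed=9)
    counted = count_mutations(str(sam), padded, primer_length=30, min_depth=0)
    np.testing.assert_array_equal(counted.depth[30:150], prof.depth)
    np.testing.assert_array_equal(counted.mutation_events[30:150], prof.mutation_events)


@given(st.integers(0, 199), st.integers(1, 40))
@settings(max_examples=50)
def test_trim_property_end_mutations_never_counted(pos, primer):
    # adversarial read: one mismatch at an arbitrary aligned offset
    cigar = (f"{pos}=1X{199 - pos}=" if pos < 199 else "199=1X")
    prof = count_mutations([make_read(0, cigar)], 200, primer_length=primer,
                           min_depth=0)
    in_trim = pos < primer or pos >= 200 - primer
    assert prof.mutation_events.sum() == (0 if in_trim else 1)


# ---------------------------------------------------------------------------
# reactivity


def test_reactivity_arithmetic():
    t = profile_of([10000], [20])  # rate 0.002
    c = profile_of([10000], [5])  # rate 0.0005
    r = reactivity(t, c)
    assert r.reactivity[0] == pytest.approx(0.0015)


def test_reactivity_identical_profiles_zero():
    p = profile_of([100, 200], [1, 2])
    assert np.allclose(reactivity(p, p).reactivity, 0.0)


def test_reactivity_undefined_without_coverage():
    t = profile_of([100, 0], [1, 0])
    c = profile_of([100, 100], [0, 0])
    r = reactivity(t, c)
    assert np.isnan(r.reactivity[1]) and not r.profiled_mask[1]


def test_reactivity_length_mismatch_errors():
    with pytest.raises(ValueError, match="mismatch"):
        reactivity(profile_of([1], [0]), profile_of([1, 1], [0, 0]))


def test_reactivity_estimate_unbiased_over_seeds():
    # binomial expectation: mean estimate within 3 sigma of truth
    true_r, bg, depth, n = 0.002, 0.0002, 50000, 100
    ests = []
    for seed in range(n):
        profs, _ = gen_shape_profiles(20, true_r, bg, depth,
                                      ("treated", "control"), seed=seed)
        ests.append(np.mean(reactivity(profs[0], profs[1]).reactivity))
    se = np.sqrt((true_r + bg) / depth + bg / depth) / np.sqrt(20 * n)
    assert abs(np.mean(ests) - true_r) < 3 * se
    assert abs(np.mean(ests) - true_r) < 2e-4


# ---------------------------------------------------------------------------
# profiled positions / positive calls


def test_profiled_depth_boundary_is_strict():
    a = profile_of([10000, 10001], [0, 0])
    b = profile_of([10001, 10001], [0, 0])
    assert list(profiled_positions([a, b], 10000)) == [2]


def test_profiled_all_above():
    a = profile_of([10001, 10001], [0, 0])
    assert list(profiled_positions([a], 10000)) == [1, 2]


def test_profiled_intersection_monotone(rng):
    profs = [profile_of(rng.integers(0, 20001, 30), np.zeros(30)) for _ in range(4)]
    prev = None
    for i in range(1, 5):
        cur = set(profiled_positions(profs[:i], 10000))
        if prev is not None:
            assert cur <= prev
        prev = cur


def test_profiled_monotone_in_min_reads(rng):
    profs = [profile_of(rng.integers(0, 20001, 30), np.zeros(30))]
    assert set(profiled_positions(profs, 12000)) <= set(profiled_positions(profs, 8000))


def test_positive_call_boundary_strict():
    p = profile_of([100000, 100000, 100000], [100, 200, 0], min_depth=0)
    # rates: exactly 0.001, 0.002, 0
    assert list(positive_calls(p, 0.001)) == [2]


def test_positive_calls_empty_on_zero_profile():
    p = profile_of([100000] * 5, [0] * 5, min_depth=0)
    assert len(positive_calls(p, 0.001)) == 0


def test_positive_calls_ignore_low_depth_positions():
    p = profile_of([100, 100000], [10, 500], min_depth=5000)
    assert list(positive_calls(p, 0.001)) == [2]


def test_merge_amplicons_sums_overlap():
    a = profile_of([10, 10], [1, 0])
    b = profile_of([5, 5], [0, 2])
    merged = merge_amplicons([(a, 0), (b, 1)], 3)
    np.testing.assert_array_equal(merged.depth, [10, 15, 5])
    np.testing.assert_array_equal(merged.mutation_events, [1, 0, 2])


# ---------------------------------------------------------------------------
# PCA


def react_of(values):
    v = np.asarray(values, dtype=float)
    from xcikit.shape import ReactivityProfile

    return ReactivityProfile(reactivity=v, profiled_mask=np.ones(len(v), bool))


def test_pca_identical_profiles_zero_variance():
    r = react_of([0.1, 0.2, 0.3])
    res = pca_profiles([r, r], np.array([1, 2, 3]))
    assert np.allclose(res.scores[0], res.scores[1])
    assert res.explained_variance_ratio[0] == 0.0


def test_pca_requires_two_samples():
    with pytest.raises(ValueError, match="2 samples"):
        pca_profiles([react_of([1.0])], np.array([1]))


def test_pca_explained_variance_valid():
    rng = np.random.default_rng(0)
    rs = [react_of(rng.normal(size=40)) for _ in range(5)]
    res = pca_profiles(rs, np.arange(1, 41))
    evr = res.explained_variance_ratio
    assert ((evr >= -1e-12) & (evr <= 1 + 1e-12)).all()
    assert (np.diff(evr) <= 1e-12).all()
    assert evr.sum() <= 1 + 1e-9


def test_pca_matches_eigendecomposition_oracle(rng):
    # oracle: full eigen-decomposition of the covariance of centered data
    for _ in range(5):
        n, p = int(rng.integers(3, 10)), int(rng.integers(5, 100))
        mat = rng.normal(size=(n, p))
        rs = [react_of(row) for row in mat]
        res = pca_profiles(rs, np.arange(1, p + 1), n_components=n - 1)
        centered = mat - mat.mean(axis=0)
        cov = centered.T @ centered / (n - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        for i in range(n - 1):
            comp = v[:, i]
            j = int(np.argmax(np.abs(comp)))
            if comp[j] < 0:
                comp = -comp
            scores = centered @ comp
            np.testing.assert_allclose(res.scores[:, i], scores, atol=1e-8)
        total = w.sum()
        np.testing.assert_allclose(
            res.explained_variance_ratio, w[: n - 1] / total, atol=1e-10
        )


def test_pca_separates_perturbed_condition_over_seeds():
    # duplicated wild-type pair vs perturbed pair: PC1 separates in >= 95%
    rng = np.random.default_rng(7)
    L, depth = 100, 20000
    base = np.zeros(L)
    base[::5] = 0.004
    perturbed = np.roll(base, 2)
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        wt, _ = gen_shape_profiles(L, base, 2e-4, depth, ("treated", "treated"),
                                   seed=seed)
        mu, _ = gen_shape_profiles(L, perturbed, 2e-4, depth,
                                   ("treated", "treated"), seed=10_000 + seed)
        ctrl, _ = gen_shape_profiles(L, 0.0, 2e-4, depth, ("control",),
                                     seed=20_000 + seed)
        rs = [reactivity(p, ctrl[0]) for p in wt + mu]
        res = pca_profiles(rs, np.arange(1, L + 1))
        pc1 = res.scores[:, 0]
        if max(pc1[:2]) < min(pc1[2:]) or min(pc1[:2]) > max(pc1[2:]):
            hits += 1
    assert hits >= 0.95 * n_seeds
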