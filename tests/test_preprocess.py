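"""QC flag rule, orientation, scale normalization and averaging."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipchip.io import SignalBundle
from chipchip.preprocess import (
    REASON_BOTH_STRAINS,
    REASON_MORE_THAN_TWO,
    apply_flag_filter,
    median_center,
    orient_matrix,
    orient_ratio,
    scale_normalize,
    strain_average,
)


def _bundle_with_flags(flag_spec):
    """One probe, 4 samples (comp r1/r2, del r1/r2); flag_spec maps sample
    index -> channels flagged (set of 0/1)."""
    probes = pd.DataFrame({"probe_id": ["p0"], "chrom": "chr", "start": [1], "end": [60]})
    samples = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "d1", "d2"],
            "strain": ["comp", "comp", "del", "del"],
            "timepoint": [14.0] * 4,
            "replicate": [1, 2, 1, 2],
            "assay": ["chip"] * 4,
            "ip_dye": ["Cy5", "Cy3", "Cy5", "Cy3"],
        }
    )
    flags = np.zeros((1, 4, 2), dtype=bool)
    for j, channels in flag_spec.items():
        for k in channels:
            flags[0, j, k] = True
    return SignalBundle(probes=probes, samples=samples,
                        raw_log2=np.zeros((1, 4)), flags=flags)


@pytest.mark.parametrize(
    "flag_spec, excluded, reason",
    [
        # both channels in comp rep1 and del rep2 -> both strains
        ({0: {0, 1}, 3: {0, 1}}, True, REASON_BOTH_STRAINS),
        # both channels in comp rep1 and rep2 only (2 samples, one strain)
        ({0: {0, 1}, 1: {0, 1}}, False, None),
        # three fully flagged samples -> excluded; both_strains takes precedence
        ({0: {0, 1}, 1: {0, 1}, 2: {0, 1}}, True, REASON_BOTH_STRAINS),
        # one channel only in one sample -> zero flagged samples
        ({0: {0}}, False, None),
        # single-channel flags in every sample still count zero flagged samples
        ({0: {0}, 1: {1}, 2: {0}, 3: {1}}, False, None),
    ],
    ids=["both_strains", "two_same_strain", "three_samples", "one_channel", "mixed_channels"],
)
def test_flag_exclusion_rule(flag_spec, excluded, reason):
    report = apply_flag_filter(_bundle_with_flags(flag_spec), 14.0)
    assert ("p0" in report.excluded_probe_ids) == excluded
    if excluded:
        assert report.reasons["p0"] == reason


def test_more_than_two_reason_reported_for_single_strain_overflow():
    # 3 replicates of one strain flagged, none of the other
    probes = pd.DataFrame({"probe_id": ["p0"], "chrom": "chr", "start": [1], "end": [60]})
    samples = pd.DataFrame(
        {
            "sample_id": ["c1", "c2", "c3", "d1", "d2", "d3"],
            "strain": ["comp"] * 3 + ["del"] * 3,
            "timepoint": [14.0] * 6,
            "replicate": [1, 2, 3, 1, 2, 3],
            "assay": ["chip"] * 6,
            "ip_dye": ["Cy5", "Cy3", "Cy5", "Cy3", "Cy5", "Cy3"],
        }
    )
    flags = np.zeros((1, 6, 2), dtype=bool)
    flags[0, :3, :] = True
    bundle = SignalBundle(probes=probes, samples=samples,
                          raw_log2=np.zeros((1, 6)), flags=flags)
    report = apply_flag_filter(bundle, 14.0)
    assert report.reasons["p0"] == REASON_MORE_THAN_TWO


def test_flag_filter_requires_present_timepoint():
    with pytest.raises(ValueError, match="absent"):
        apply_flag_filter(_bundle_with_flags({}), 99.0)


@given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1))
@settings(max_examples=60, deadline=None)
def test_adding_flags_never_rescues_an_excluded_probe(bits_a, bits_b):
    """Flag monotonicity: flags_b superset of flags_a cannot un-exclude."""
    base = np.array([(bits_a >> i) & 1 for i in range(8)], bool).reshape(1, 4, 2)
    extra = np.array([(bits_b >> i) & 1 for i in range(8)], bool).reshape(1, 4, 2)
    spec_a = {j: {k for k in range(2) if base[0, j, k]} for j in range(4)}
    more = base | extra
    spec_b = {j: {k for k in range(2) if more[0, j, k]} for j in range(4)}
    rep_a = apply_flag_filter(_bundle_with_flags(spec_a), 14.0)
    rep_b = apply_flag_filter(_bundle_with_flags(spec_b), 14.0)
    assert rep_a.excluded_probe_ids <= rep_b.excluded_probe_ids


@pytest.mark.parametrize(
    "raw, dye, expected",
    [(1.0, "Cy5", 1.0), (-0.8, "Cy3", 0.8), (0.0, "Cy5", 0.0), (0.0, "Cy3", 0.0)],
)
def test_orientation_correction(raw, dye, expected):
    assert orient_ratio(raw, dye) == expected


def test_unknown_dye_label_rejected():
    with pytest.raises(ValueError, match="unknown dye"):
        orient_ratio(1.0, "Cy9")


def test_dye_swap_symmetry_is_bit_exact(tiny_bundle):
    """Negating raw values and flipping every dye label leaves the oriented
    matrix unchanged."""
    oriented = orient_matrix(tiny_bundle)
    flipped = tiny_bundle
    flipped.raw_log2 = -flipped.raw_log2
    flipped.samples["ip_dye"] = flipped.samples["ip_dye"].map({"Cy5": "Cy3", "Cy3": "Cy5"})
    assert np.array_equal(orient_matrix(flipped), oriented)


def test_scale_normalization_worked_example():
    # arrays A={-2,-1,1,2} (m=1.5), B={-4,-2,2,4} (m=3); g = sqrt(4.5)
    matrix = np.array([[-2.0, -4.0], [-1.0, -2.0], [1.0, 2.0], [2.0, 4.0]])
    norm = scale_normalize(matrix)
    g = np.sqrt(4.5)
    np.testing.assert_allclose(norm.scale_factors, [g / 1.5, g / 3.0], rtol=1e-12)
    np.testing.assert_allclose(
        np.median(np.abs(norm.values), axis=0), [g, g], rtol=1e-12
    )


def test_scale_normalization_single_array_is_identity():
    matrix = np.array([[1.0], [-2.0], [3.0]])
    norm = scale_normalize(matrix)
    np.testing.assert_array_equal(norm.values, matrix)


def test_scale_normalization_rejects_all_zero_array():
    with pytest.raises(ValueError, match="degenerate"):
        scale_normalize(np.array([[1.0, 0.0], [2.0, 0.0]]))


def test_scale_normalization_unit_policy_leaves_degenerate_array_alone():
    matrix = np.array([[1.0, 0.0], [-2.0, 0.0], [3.0, 0.0]])
    norm = scale_normalize(matrix, on_degenerate="unit")
    assert norm.scale_factors[1] == 1.0
    np.testing.assert_array_equal(norm.values[:, 1], 0.0)


def test_scale_normalization_is_idempotent():
    rng = np.random.default_rng(3)
    matrix = rng.normal(0, 1, (51, 4)) * np.array([0.5, 1.0, 2.0, 4.0])
    once = scale_normalize(matrix).values
    twice = scale_normalize(once).values
    np.testing.assert_allclose(twice, once, atol=1e-9)


def test_scale_normalization_matches_limma_reference():
    """Independent oracle: limma's median-absolute-value scaling in R."""
    rng = np.random.default_rng(9)
    matrix = rng.normal(0, 1, (21, 3)) * np.array([0.5, 1.5, 3.0])
    ours = scale_normalize(matrix).values
    rows = ";".join(",".join(f"{v:.15g}" for v in row) for row in matrix)
    script = (
        "suppressMessages(library(limma));"
        f"m <- do.call(rbind, lapply(strsplit(strsplit('{rows}', ';')[[1]], ','), as.numeric));"
        "out <- normalizeMedianAbsValues(m);"
        "cat(sprintf('%.10f', out), sep='\\n')"
    )
    proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
    assert proc.returncode == 0, proc.stderr
    ref = np.array([float(x) for x in proc.stdout.split()]).reshape(matrix.shape, order="F")
    np.testing.assert_allclose(ours, ref, atol=1e-8)


@pytest.mark.parametrize(
    "column, expected",
    [
        ([1.0, 2.0, 3.0], [-1.0, 0.0, 1.0]),
        ([-1.0, 0.0, 1.0], [-1.0, 0.0, 1.0]),
        ([1.0, 2.0, 3.0, 4.0], [-1.5, -0.5, 0.5, 1.5]),  # even n: mean of middle two
    ],
)
def test_median_centering(column, expected):
    out = median_center(np.array(column)[:, None])
    np.testing.assert_allclose(out[:, 0], expected)


def test_median_centering_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        median_center(np.empty((0, 1)))


def test_expression_order_leaves_final_per_array_median_zero():
    """median-center then scale: symmetric arrays keep per-array median 0."""
    rng = np.random.default_rng(4)
    half = rng.normal(0, 1, (100, 3))
    matrix = np.vstack([half, -half]) + np.array([0.5, -1.0, 2.0])
    out = scale_normalize(median_center(matrix)).values
    np.testing.assert_allclose(np.median(out, axis=0), 0.0, atol=1e-9)


def test_strain_average(tiny_bundle):
    values = orient_matrix(tiny_bundle)
    avg = strain_average(values, tiny_bundle.samples, "comp")
    np.testing.assert_allclose(avg, values[:, :2].mean(axis=1))
    # a probe missing one replicate averages over the rest
    values[0, 0] = np.nan
    avg = strain_average(values, tiny_bundle.samples, "comp")
    assert avg[0] == values[0, 1]
    # opposite replicate values cancel
    values[1, 0], values[1, 1] = 0.7, -0.7
    avg = strain_average(values, tiny_bundle.samples, "comp")
    assert avg[1] == 0.0


def test_strain_average_requires_replicates(tiny_bundle):
    with pytest.raises(ValueError, match="no replicates"):
        strain_average(tiny_bundle.raw_log2, tiny_bundle.samples, "missing_strain")
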