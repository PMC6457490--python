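"""Enrichment calling, clustering, annotation and peak-shape classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chipchip.binding import (
    ClusterParams,
    ShapeParams,
    annotate_regions,
    BindingRegion,
    call_enriched_probes,
    classify_peak_shape,
    cluster_regions,
)
from chipchip.io import GenomeAnnotation
from chipchip.simulate import TrueRegion, spike_profile


def _probe_set(fold_changes, candidates=None):
    """Build replicate matrices realizing given fold changes; every probe is
    a candidate unless listed otherwise (deleted reps at 0)."""
    fc = np.asarray(fold_changes, float)
    comp = np.column_stack([fc, fc])
    dele = np.zeros_like(comp)
    if candidates is not None:
        for i, ok in enumerate(candidates):
            if not ok:
                dele[i, 1] = comp[i, 1] + 1.0  # break the strict inequality in rep 2
    return call_enriched_probes(comp, dele)


class TestEnrichmentCalling:
    def test_worked_example_mean_plus_one_sd_threshold(self):
        """Candidates {0.2,0.4,0.6,0.8,3.0}: mean 1.0, sample sd 1.1402,
        threshold 2.1402, exactly the 3.0 probe enriched."""
        res = _probe_set([0.2, 0.4, 0.6, 0.8, 3.0])
        assert res.n_candidates == 5
        assert res.fc_mean == pytest.approx(1.0)
        assert res.fc_sd == pytest.approx(np.sqrt(1.3), rel=1e-12)
        assert res.threshold == pytest.approx(1.0 + np.sqrt(1.3), rel=1e-12)
        assert res.is_enriched.tolist() == [False, False, False, False, True]

    def test_candidate_requires_strict_win_in_every_replicate(self):
        comp = np.array([[1.0, 0.2]])
        dele = np.array([[0.5, 0.5]])
        with pytest.warns(UserWarning):  # a single candidate remains
            res = call_enriched_probes(np.vstack([comp, comp + 5]), np.vstack([dele, dele - 9]))
        assert not res.is_candidate[0]  # rep2 0.2 < 0.5 despite large fold change
        assert res.is_candidate[1]

    def test_identical_fold_changes_give_zero_sd_and_no_calls(self):
        res = _probe_set([0.7, 0.7, 0.7])
        assert res.fc_sd == pytest.approx(0.0, abs=1e-12)
        assert res.threshold == pytest.approx(0.7)
        assert not res.is_enriched.any()  # strict ">"

    def test_fewer_than_two_candidates_warns_and_calls_nothing(self):
        with pytest.warns(UserWarning, match="candidate"):
            res = _probe_set([0.5, 0.8, 1.2], candidates=[True, False, False])
        assert np.isnan(res.threshold)
        assert not res.is_enriched.any()

    def test_enriched_subset_of_candidates(self):
        rng = np.random.default_rng(2)
        res = call_enriched_probes(rng.normal(0, 1, (300, 2)), rng.normal(0, 1, (300, 2)))
        assert not (res.is_enriched & ~res.is_candidate).any()

    @given(st.floats(-0.09, 5))  # keep every probe a strict candidate
    @settings(max_examples=40, deadline=None)
    def test_threshold_equivariance_under_constant_shift(self, c):
        """Adding c to every fold change shifts the threshold by c and leaves
        the enriched set unchanged."""
        fc = [0.1, 0.3, 0.9, 1.4, 4.0]
        base = _probe_set(fc)
        shifted = call_enriched_probes(
            np.column_stack([np.array(fc) + c] * 2) + 10.0,
            np.full((5, 2), 10.0),
        )
        assert shifted.threshold == pytest.approx(base.threshold + c, abs=1e-9)
        assert np.array_equal(shifted.is_enriched, base.is_enriched)

    def test_contrast_asymmetry(self):
        """Swapping strain roles leaves no candidates where candidates were."""
        rng = np.random.default_rng(7)
        comp = rng.normal(0.5, 1, (200, 2))
        dele = rng.normal(0.0, 1, (200, 2))
        fwd = call_enriched_probes(comp, dele)
        rev = call_enriched_probes(dele, comp)
        assert not (fwd.is_candidate & rev.is_candidate).any()


def _enriched_frame(midpoints, fc=None):
    mids = np.asarray(midpoints, float)
    fc = np.ones_like(mids) if fc is None else np.asarray(fc, float)
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(mids))],
            "chrom": "chr",
            "start": (mids - 10).astype(int),
            "end": (mids + 10).astype(int),
            "fold_change": fc,
        }
    )


def _brute_force_clusters(midpoints, max_gap):
    """Transitive closure over all pairs with gap <= max_gap (oracle)."""
    n = len(midpoints)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(midpoints[i] - midpoints[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(midpoints[i])
    return sorted(sorted(g) for g in groups.values())


class TestClustering:
    def test_three_probes_within_gap_form_one_region(self):
        regions = cluster_regions(_enriched_frame([100, 600, 1090]), ClusterParams())
        assert len(regions) == 1
        assert regions[0].n_probes == 3
        assert (regions[0].start, regions[0].end) == (90, 1100)

    def test_singleton_cluster_is_dropped(self):
        regions = cluster_regions(_enriched_frame([100, 600, 2000]), ClusterParams())
        assert len(regions) == 1
        assert regions[0].probe_ids == ["p0", "p1"]

    def test_gap_exactly_at_boundary_joins(self):
        regions = cluster_regions(_enriched_frame([500, 1500]), ClusterParams())
        assert len(regions) == 1

    def test_empty_input_gives_no_regions(self):
        assert cluster_regions(_enriched_frame([]), ClusterParams()) == []

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(42)
        params = ClusterParams(max_gap=1000, min_probes=1)
        for _ in range(300):
            n = rng.integers(1, 30)
            mids = np.sort(rng.choice(np.arange(100, 50_000, 20), size=n, replace=False))
            regions = cluster_regions(_enriched_frame(mids), params)
            got = sorted(
                sorted((np.asarray(mids)[[int(p[1:]) for p in r.probe_ids]]).tolist())
                for r in regions
            )
            assert got == _brute_force_clusters(mids.tolist(), 1000)

    def test_span_method_splits_long_chains(self):
        # chain of 5 probes 800 bp apart: single-linkage keeps one region,
        # the fixed-span reading splits it into <=1 kb pieces
        mids = [1000, 1800, 2600, 3400, 4200]
        gap = cluster_regions(_enriched_frame(mids), ClusterParams(method="gap"))
        span = cluster_regions(_enriched_frame(mids), ClusterParams(method="span"))
        assert len(gap) == 1
        assert len(span) >= 2
        for r in span:
            member_mids = [mids[int(p[1:])] for p in r.probe_ids]
            assert max(member_mids) - min(member_mids) <= 1000


def _annotation(genes):
    return GenomeAnnotation(
        genes=pd.DataFrame(
            [{"gene_id": g[0], "chrom": "chr", "start": g[1], "end": g[2], "strand": g[3]}
             for g in genes]
        )
    )


class TestAnnotation:
    def test_region_overlapping_upstream_window_is_promoter_proximal(self):
        region = BindingRegion("r1", "chr", 100, 300)
        ann = _annotation([("g1", 250, 900, "+")])
        annotate_regions([region], ann, promoter_window=300)
        assert region.location_class == "promoter_proximal"
        assert region.overlapping_genes == ["g1"]

    def test_region_inside_gene_is_gene_internal(self):
        region = BindingRegion("r1", "chr", 400, 500)
        ann = _annotation([("g1", 250, 900, "+")])
        annotate_regions([region], ann)
        assert region.location_class == "gene_internal"

    def test_region_in_gene_desert_is_intergenic(self):
        region = BindingRegion("r1", "chr", 5000, 5200)
        ann = _annotation([("g1", 250, 900, "+")])
        annotate_regions([region], ann)
        assert region.location_class == "intergenic"
        assert region.overlapping_genes == []

    def test_minus_strand_promoter_window_is_downstream_of_gene_end(self):
        region = BindingRegion("r1", "chr", 950, 1100)
        ann = _annotation([("g1", 250, 900, "-")])
        annotate_regions([region], ann, promoter_window=300)
        assert region.location_class == "promoter_proximal"

    def test_unknown_chromosome_rejected(self):
        region = BindingRegion("r1", "chrX", 100, 200)
        ann = _annotation([("g1", 250, 900, "+")])
        with pytest.raises(ValueError, match="unknown chromosome"):
            annotate_regions([region], ann)


class TestPeakShape:
    positions = np.arange(100.0, 4100.0, 80.0)

    def _classify(self, profile, threshold=0.5, **kw):
        region = BindingRegion("r1", "chr", 1000, 3000)
        return classify_peak_shape(region, self.positions, profile, threshold, **kw)

    def test_single_gaussian_is_monophasic(self):
        spike = TrueRegion(center=2000, amplitude=2.0, width=120.0)
        region = self._classify(spike_profile(spike, self.positions))
        assert region.shape == "monophasic"
        assert len(region.summits) == 1
        assert abs(region.summits[0] - 2000) <= 80

    def test_noise_free_biphasic_spike_recovered_with_major_summit_first(self):
        spike = TrueRegion(center=1800, shape="biphasic", amplitude=2.0, width=120.0,
                           peak_separation=600.0, amplitude_ratio=0.5)
        region = self._classify(spike_profile(spike, self.positions))
        assert region.shape == "biphasic"
        assert abs(region.summits[0] - 1800) <= 80  # major first
        assert abs(region.summits[1] - 2400) <= 80

    def test_shallow_trough_stays_monophasic(self):
        # two maxima whose trough only dips 10% below the smaller one
        profile = np.zeros_like(self.positions)
        profile[20:31] = [1.8, 1.9, 2.0, 1.9, 1.85, 1.8, 1.85, 1.9, 1.95, 1.9, 1.8]
        region = self._classify(profile, threshold=0.5)
        assert region.shape == "monophasic"

    def test_all_missing_profile_is_unclassified(self):
        region = self._classify(np.full_like(self.positions, np.nan))
        assert region.shape == "unclassified"
        assert region.summits == []

    def test_close_double_peak_below_separation_is_monophasic(self):
        spike = TrueRegion(center=2000, shape="biphasic", amplitude=2.0, width=120.0,
                           peak_separation=80.0, amplitude_ratio=0.9)
        region = self._classify(spike_profile(spike, self.positions))
        assert region.shape == "monophasic"

    def test_shape_params_validation(self):
        with pytest.raises(ValueError):
            ShapeParams(smooth_window=0)
        with pytest.raises(ValueError):
            ShapeParams(min_prominence_frac=1.5)
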