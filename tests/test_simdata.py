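"""Generator sanity: determinism, mixture structure, planted-marker truth."""

import io

import numpy as np
import pytest
from scipy import stats

from evbiomark import (
    SimulationConfig,
    build_toy_annotation,
    simulate_alignments,
    simulate_dataset,
)
from evbiomark.annotation import BIOTYPES
from evbiomark.simdata import (
    SimConfigError,
    baseline_weights,
    expected_proportions,
    feature_catalog,
    simulate_panel_markers,
)
from conftest import small_config


@pytest.mark.parametrize(
    "overrides, field",
    [
        ({"biotype_proportions": {b: 0.1 for b in BIOTYPES[:5]}}, "biotype_proportions"),
        ({"marker_prevalence": 1.5}, "marker_prevalence"),
        ({"postop_residual": -0.1}, "postop_residual"),
        ({"dispersion": -1.0}, "dispersion"),
        ({"n_hc": 0}, "n_hc"),
        ({"tau_alpha": 0.0}, "tau_alpha"),
        ({"n_features_per_biotype": 1, "n_planted_per_biotype": 2}, "n_planted_per_biotype"),
    ],
)
def test_invalid_config_names_offending_field(overrides, field):
    config = SimulationConfig(**overrides)
    with pytest.raises(SimConfigError, match=field):
        config.validate()


def test_feature_count_and_overlaps_by_construction():
    config = small_config(n_features_per_biotype=10, overlap_fraction=0.5)
    features = build_toy_annotation(config)
    assert len(features) == 100
    # at least one same-strand cross-biotype overlapping pair
    pairs = [
        (a, b)
        for i, a in enumerate(features)
        for b in features[i + 1 :]
        if a.chrom == b.chrom
        and a.strand == b.strand
        and a.biotype != b.biotype
        and min(a.end, b.end) > max(a.start, b.start)
    ]
    assert pairs


def test_zero_overlap_fraction_gives_disjoint_features():
    config = small_config(overlap_fraction=0.0)
    features = build_toy_annotation(config)
    by_chrom = {}
    for f in features:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for intervals in by_chrom.values():
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2


def test_annotation_deterministic_given_seed(tmp_path):
    from evbiomark.annotation import write_gtf

    def render(seed, tag):
        feats = build_toy_annotation(small_config(seed=seed))
        path = tmp_path / f"{tag}.gtf"
        write_gtf(feats, path)
        return path.read_text()

    assert render(3, "a") == render(3, "b")
    assert render(3, "c") != render(4, "d")


def test_dataset_reproducible_and_seed_sensitive():
    a1 = simulate_dataset(small_config(seed=7))
    a2 = simulate_dataset(small_config(seed=7))
    b = simulate_dataset(small_config(seed=8))
    assert a1[0].counts.equals(a2[0].counts)
    assert a1[1].table.equals(a2[1].table)
    assert a1[2].carrier_map == a2[2].carrier_map
    assert not a1[0].counts.equals(b[0].counts)


def test_carrier_counts_match_binomial_expectation():
    # prevalence 0.2 x 32 patients -> 6.4 expected carriers per planted marker
    config = small_config(n_features_per_biotype=2, n_planted_per_biotype=1)
    totals = []
    for seed in range(200):
        config.seed = seed
        _, _, truth = simulate_dataset(config)
        per_marker = {m: 0 for m in truth.planted_markers}
        for carried in truth.carrier_map.values():
            for m in carried:
                per_marker[m] += 1
        totals.extend(per_marker.values())
    assert abs(np.mean(totals) - 6.4) < 0.5


def test_library_sizes_track_configured_distribution():
    config = small_config()
    mean, cv = config.lib_size_mean, config.lib_size_cv
    # library sizes are lognormal (patient ones further scaled by the
    # lognormal subject effect), so the 5-SD envelope lives on the log scale
    sigma_log = np.sqrt(np.log(1 + cv**2) + config.subject_sd**2)
    mu_log = np.log(mean) - 0.5 * np.log(1 + cv**2)
    for seed in range(20):
        config.seed = seed
        cm, _, _ = simulate_dataset(config)
        log_tot = np.log(cm.counts.sum(0).to_numpy())
        assert (np.abs(log_tot - mu_log) < 5 * sigma_log).all()


def test_zero_tumor_fraction_makes_groups_identical_in_law():
    # tau ~ Beta(1e-8, 8) is numerically zero, so PreOp and HC counts share
    # one distribution; KS on pooled normalized counts should not reject.
    n_sig = 0
    for seed in range(20):
        config = small_config(seed=seed, tau_alpha=1e-8)
        cm, samples, _ = simulate_dataset(config)
        norm = cm.counts / cm.counts.sum(0)
        hc = norm[samples.samples_in_group("HC")].to_numpy().ravel()
        pre = norm[samples.samples_in_group("PreOp")].to_numpy().ravel()
        if stats.ks_2samp(hc, pre).pvalue < 0.01:
            n_sig += 1
    assert n_sig <= 2


def test_mixture_expectations_shift_composition_in_configured_directions():
    config = small_config()
    catalog = feature_catalog(config).set_index("feature_id")
    base = expected_proportions(config, tau=0.0, carried=set())
    pre = expected_proportions(config, tau=0.3, carried=set())
    for biotype, shift in config.composition_shift.items():
        b0 = base[catalog["biotype"] == biotype].sum()
        b1 = pre[catalog["biotype"] == biotype].sum()
        if shift > 1:
            assert b1 > b0
        elif shift < 1:
            assert b1 < b0


def test_planted_marker_expectation_monotone_in_postop_residual():
    config = small_config()
    truth_marker = feature_catalog(config).query("planted").feature_id.iloc[0]
    tau = 0.4
    levels = [
        expected_proportions(config, tau=r * tau, carried={truth_marker})[truth_marker]
        for r in [0.0, 0.1, 0.5, 1.0]
    ]
    assert levels == sorted(levels)
    assert levels[0] == 0.0  # tumor-specific: zero baseline


def test_planted_markers_absent_from_controls():
    cm, samples, truth = simulate_dataset(small_config(seed=2))
    hc = samples.samples_in_group("HC")
    assert (cm.counts.loc[sorted(truth.planted_markers), hc] == 0).all().all()


def test_alignment_stream_deterministic_and_truth_matches_priority():
    config = small_config(n_reads_per_sample=300)
    annotation = build_toy_annotation(config)
    aln1, truth1 = simulate_alignments(config, annotation)
    aln2, truth2 = simulate_alignments(config, annotation)
    assert truth1.equals(truth2)
    assert aln1 == aln2
    # conservation: every read got a truth label or none; labels <= reads
    for s, records in aln1.items():
        assert truth1[s].sum() <= len(records)


def test_alignments_in_disjoint_annotation_equal_naive_counts():
    config = small_config(overlap_fraction=0.0, n_reads_per_sample=300)
    annotation = build_toy_annotation(config)
    _, truth = simulate_alignments(config, annotation)
    # with no overlaps every read stays on its emitting feature, so all
    # reads are assigned (reads never fall outside features by construction)
    assert truth.sum().sum() == 2 * config.n_reads_per_sample


def test_empty_annotation_rejected():
    with pytest.raises(ValueError, match="empty"):
        simulate_alignments(small_config(), [])


def test_panel_fixture_structure():
    X, y, informative = simulate_panel_markers(seed=0)
    assert X.shape == (62, 50)
    assert len(informative) == 8
    assert y.sum() == 32
    cases = X.loc[y == 1, informative].to_numpy()
    controls = X.loc[y == 0, informative].to_numpy()
    assert (controls == 0).all()  # tumor-specific: never in controls
    assert ((cases > 0).sum(axis=1) >= 1).all()  # every case covered
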