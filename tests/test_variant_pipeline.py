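"""Tests of masks, QC, calling, distances, and rate arithmetic."""

import numpy as np
import pandas as pd
import pytest

from odrift.variant_pipeline import (
    GenomeAnnotation,
    call_fixed,
    call_heteroplasmic,
    coverage_proportion,
    estimate_copy_number,
    genetic_distance,
    load_records,
    neutral_mask,
    sample_and_position_qc,
    substitution_rate,
    summarize_alleles,
    write_records,
    write_vcf,
)


def _records(rows):
    """rows: (sample, organelle, pos, ref, coverage, A, C, G, T)"""
    return pd.DataFrame(rows, columns=["sample", "organelle", "pos", "ref",
                                       "coverage", "A", "C", "G", "T"])


def _uniform_records(sample, organelle, length, cov, ref="A", overrides=None):
    df = _records([(sample, organelle, p, ref, cov,
                    cov if ref == "A" else 0, 0, 0,
                    cov if ref == "T" else 0)
                   for p in range(1, length + 1)])
    for pos, cols in (overrides or {}).items():
        for col, val in cols.items():
            df.loc[df["pos"] == pos, col] = val
    return df


class TestCoverageProportion:
    def test_values(self):
        assert coverage_proportion(985, 985) == pytest.approx(1.0)
        assert coverage_proportion(300, 1000) == pytest.approx(0.3)
        assert coverage_proportion(1600, 1000) == pytest.approx(1.6)
        with pytest.raises(ValueError):
            coverage_proportion(10, 0)


class TestNeutralMask:
    def test_empty_annotation_is_fully_neutral(self):
        ann = GenomeAnnotation(genome_length=100)
        for mode in ("fixed", "heteroplasmy"):
            assert neutral_mask(ann, "mt", mode).sum() == 100

    def test_repeat_halo(self):
        # a 9-bp poly-A at 1-based 50-58 excludes 48-60 (+/- 2 bp halo)
        ann = GenomeAnnotation(genome_length=100, repeats=[(49, 58)])
        mask = neutral_mask(ann, "mt", "fixed")
        excluded = np.flatnonzero(~mask) + 1
        assert excluded.tolist() == list(range(48, 61))

    def test_plastid_inverted_repeats_excluded_for_heteroplasmy(self):
        ann = GenomeAnnotation(genome_length=120_000,
                               inverted_repeats=[(90_000, 115_000)])
        het = neutral_mask(ann, "pt", "heteroplasmy")
        assert not het[90_000:115_000].any()
        fixed = neutral_mask(ann, "pt", "fixed")
        assert fixed[90_000:115_000].all()  # IRs only excluded for heteroplasmy

    def test_shared_dna_rules_per_mode(self):
        ann = GenomeAnnotation(genome_length=1000, numt=[(100, 200)],
                               mtpt=[(300, 400)])
        fixed_mt = neutral_mask(ann, "mt", "fixed")
        assert fixed_mt[100:200].all()      # NUMTs stay for fixed mutations
        assert not fixed_mt[300:400].any()  # mtptDNA excluded in mt
        het_mt = neutral_mask(ann, "mt", "heteroplasmy")
        assert not het_mt[100:200].any() and not het_mt[300:400].any()

    def test_heteroplasmy_mask_subset_of_fixed_mask(self):
        rng = np.random.default_rng(3)
        ann = GenomeAnnotation(
            genome_length=5000,
            coding=[(100, 500)], repeats=[(1000, 1012)],
            numt=[(2000, 2200)], mtpt=[(3000, 3100)],
            inverted_repeats=[(4000, 4500)],
        )
        for org in ("mt", "pt"):
            het = neutral_mask(ann, org, "heteroplasmy")
            fixed = neutral_mask(ann, org, "fixed")
            assert not (het & ~fixed).any()

    def test_segments_must_partition(self):
        with pytest.raises(ValueError):
            GenomeAnnotation(genome_length=100, segments=[(0, 40), (50, 100)])


class TestQC:
    def test_mt_sample_median_cutoff(self):
        ann = GenomeAnnotation(genome_length=50)
        low = _uniform_records("S1", "mt", 50, 49)
        ok = _uniform_records("S2", "mt", 50, 400)
        out, log = sample_and_position_qc(pd.concat([low, ok]), ann, "mt")
        assert log.samples_dropped_low_median == ["S1"]
        assert set(out["sample"]) == {"S2"}

    def test_mt_position_coverage_and_covprop_bounds(self):
        ann = GenomeAnnotation(genome_length=50)
        df = _uniform_records("S1", "mt", 50, 1000,
                              overrides={5: {"coverage": 149},
                                         7: {"coverage": 1600},
                                         9: {"coverage": 250}})
        out, log = sample_and_position_qc(df, ann, "mt")
        gone = {5, 7, 9} - set(out["pos"])
        assert gone == {5, 7, 9}  # low coverage; covprop 1.6; covprop 0.25
        assert log.n_dropped_low_coverage == 1
        assert log.n_dropped_cov_prop == 2

    def test_pt_boundary_covprop_passes(self):
        ann = GenomeAnnotation(genome_length=50)
        df = _uniform_records("S1", "pt", 50, 1000,
                              overrides={3: {"coverage": 310},
                                         4: {"coverage": 290}})
        out, _ = sample_and_position_qc(df, ann, "pt")
        assert 3 in set(out["pos"])      # 0.31 retained
        assert 4 not in set(out["pos"])  # 0.29 dropped


class TestCalling:
    def test_fixed_threshold_inclusive(self):
        ann = GenomeAnnotation(genome_length=10)
        df = _uniform_records("S1", "mt", 10, 1000,
                              overrides={2: {"A": 250, "G": 750},
                                         3: {"A": 251, "G": 749},
                                         4: {"A": 90, "G": 910}})
        df = df.merge(pd.DataFrame({"pos": range(1, 11)}), on="pos")
        qcd, _ = sample_and_position_qc(df, ann, "mt")
        calls = call_fixed(qcd, np.ones(10, dtype=bool))
        by_pos = {int(r.pos): r for r in calls.itertuples()}
        assert 2 in by_pos and by_pos[2].af == pytest.approx(0.75)
        assert 3 not in by_pos  # 0.749
        # AF 0.91 is fixed and also inside the heteroplasmic range
        assert 4 in by_pos and by_pos[4].also_heteroplasmic_range

    def test_heteroplasmic_candidate_range_and_cluster_filter(self):
        ann = GenomeAnnotation(genome_length=200)
        over = {
            50: {"A": 490, "G": 510},            # clean candidate, AF 0.51
            100: {"A": 600, "G": 400},           # clustered pair ...
            102: {"A": 650, "G": 350},           # ... within 2 nt
            150: {"A": 40, "G": 960},            # AF 0.96: not a candidate
        }
        df = _uniform_records("S1", "mt", 200, 1000, overrides=over)
        qcd, _ = sample_and_position_qc(df, ann, "mt")
        calls, rejected = call_heteroplasmic(qcd, np.ones(200, dtype=bool), ann)
        assert set(calls["pos"]) == {50}
        assert calls.iloc[0]["af"] == pytest.approx(0.51)
        rej = {int(r.pos): r.filters_failed for r in rejected.itertuples()}
        assert set(rej) == {100, 102}
        assert all("cluster" in f for f in rej.values())

    def test_cluster_filter_is_per_sample(self):
        ann = GenomeAnnotation(genome_length=200)
        a = _uniform_records("S1", "mt", 200, 1000,
                             overrides={100: {"A": 600, "G": 400}})
        b = _uniform_records("S2", "mt", 200, 1000,
                             overrides={102: {"A": 600, "G": 400}})
        qcd, _ = sample_and_position_qc(pd.concat([a, b]), ann, "mt")
        calls, rejected = call_heteroplasmic(qcd, np.ones(200, dtype=bool), ann)
        # candidates in different samples do not cluster with each other
        assert set(calls["pos"]) == {100, 102}
        assert rejected.empty

    def test_reference_coverage_proportion_filter(self):
        ann = GenomeAnnotation(genome_length=100)
        # candidate sample: 1100 reference + 400 variant reads over a
        # median of ~1000: apparent AF 0.27 but ref alone > median
        over = {30: {"coverage": 1500, "A": 1100, "G": 400}}
        df = _uniform_records("S1", "mt", 100, 1000, overrides=over)
        qcd, _ = sample_and_position_qc(df, ann, "mt")
        calls, rejected = call_heteroplasmic(qcd, np.ones(100, dtype=bool), ann)
        assert calls.empty
        assert rejected.iloc[0]["filters_failed"] == ["ref_cov_prop"]


class TestDistancesAndRates:
    def test_identical_samples_have_zero_distance(self):
        ann = GenomeAnnotation(genome_length=50)
        a = _uniform_records("S1", "mt", 50, 1000)
        b = _uniform_records("S2", "mt", 50, 1000)
        qcd, _ = sample_and_position_qc(pd.concat([a, b]), ann, "mt")
        mask = np.ones(50, dtype=bool)
        d, sd = genetic_distance(qcd, mask, ["S1"], ["S2"])
        assert d == 0.0

    def test_pairwise_difference_count_and_symmetry(self):
        ann = GenomeAnnotation(genome_length=50)
        a = _uniform_records("S1", "mt", 50, 1000)
        b = _uniform_records("S2", "mt", 50, 1000,
                             overrides={5: {"A": 0, "G": 1000},
                                        9: {"A": 0, "C": 1000},
                                        20: {"A": 0, "T": 1000}})
        qcd, _ = sample_and_position_qc(pd.concat([a, b]), ann, "mt")
        mask = np.ones(50, dtype=bool)
        assert genetic_distance(qcd, mask, ["S1"], ["S2"])[0] == 3.0
        assert genetic_distance(qcd, mask, ["S2"], ["S1"])[0] == 3.0

    def test_cross_group_mean_over_pairs(self):
        ann = GenomeAnnotation(genome_length=100)
        frames = [_uniform_records("A1", "mt", 100, 1000),
                  _uniform_records("A2", "mt", 100, 1000,
                                   overrides={1: {"A": 0, "G": 1000},
                                              2: {"A": 0, "G": 1000}}),
                  _uniform_records("B1", "mt", 100, 1000,
                                   overrides={p: {"A": 0, "C": 1000}
                                              for p in range(10, 20)}),
                  _uniform_records("B2", "mt", 100, 1000,
                                   overrides={p: {"A": 0, "C": 1000}
                                              for p in range(10, 24)})]
        qcd, _ = sample_and_position_qc(pd.concat(frames), ann, "mt")
        mask = np.ones(100, dtype=bool)
        # pair distances: A1-B1 10, A1-B2 14, A2-B1 12, A2-B2 16 -> mean 13
        d, sd = genetic_distance(qcd, mask, ["A1", "A2"], ["B1", "B2"])
        assert d == pytest.approx(13.0)

    def test_substitution_rate_hand_arithmetic(self):
        sr = substitution_rate(56.7, 121_502, 243_300)
        assert sr.rate == pytest.approx(56.7 / (2 * 121_502 * 243_300), rel=1e-13)
        assert sr.accumulated == pytest.approx(28.35)
        with pytest.raises(ValueError):
            substitution_rate(1.0, 0, 243_300)

    def test_copy_number_estimates(self):
        assert estimate_copy_number(3240, 81) == pytest.approx(40.0)
        assert estimate_copy_number(17_496, 81) == pytest.approx(216.0)
        assert estimate_copy_number(0, 81) == 0.0
        with pytest.raises(ValueError):
            estimate_copy_number(100, 0)


class TestIO:
    def test_records_round_trip(self, tmp_path):
        df = _uniform_records("S1", "mt", 10, 100)
        path = tmp_path / "records.tsv"
        write_records(df, path)
        back = load_records(path)
        pd.testing.assert_frame_equal(df, back)

    def test_load_records_requires_schema(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"sample": ["x"], "pos": [1]}).to_csv(path, sep="\t",
                                                           index=False)
        with pytest.raises(ValueError):
            load_records(path)

    def test_minimal_vcf_output(self, tmp_path):
        calls = pd.DataFrame([
            {"sample": "S1", "organelle": "mt", "pos": 27_884, "base": "G",
             "af": 0.91, "kind": "heteroplasmic", "ref": "A"},
        ])
        path = tmp_path / "calls.vcf"
        write_vcf(calls, path, reference_name="mt")
        text = path.read_text()
        assert text.startswith("##fileformat=VCFv4.2")
        assert "27884" in text and "KIND=heteroplasmic" in text

    def test_triallelic_positions_flagged_not_called(self):
        ann = GenomeAnnotation(genome_length=20)
        over = {5: {"A": 400, "G": 300, "C": 300}}
        df = _uniform_records("S1", "mt", 20, 1000, overrides=over)
        qcd, _ = sample_and_position_qc(df, ann, "mt")
        calls, rejected = call_heteroplasmic(qcd, np.ones(20, dtype=bool), ann)
        assert calls.empty
        assert "triallelic" in rejected.iloc[0]["filters_failed"]
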