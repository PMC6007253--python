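import numpy as np
import pandas as pd
import pytest

from netdlnc.catalogue import TranscriptRecord
from netdlnc.clinical import (
    ProbeRegion,
    ddct_fold_change,
    define_rapid_met_groups,
    km_median_split,
    map_probes,
    rank_class_transcripts,
    roc_auc,
    summarize_probe_expression,
)
from netdlnc.synthetic_data import (
    SimulationConfig,
    generate_outcome_cohort,
    generate_probe_map,
    synthetic_catalogue,
)


def pair_counting_auc(scores, labels):
    """Independent oracle: exhaustive positive/negative pair counting."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRanking:
    def test_class_i_uses_minimum_fold_change(self):
        sets = {"I_Deactivated": {"t1", "t2"}}
        fcs = {
            "NEPC_vs_AD": {"t1": 0.1, "t2": 0.3},
            "CRPC_vs_AD": {"t1": 0.2, "t2": 0.2},
            "NHT_vs_NAIVE": {"t1": 0.3, "t2": 0.25},
        }
        selections, _ = rank_class_transcripts(sets, fcs)
        assert selections["I_Deactivated"] == ["t1", "t2"]  # min 0.1 beats 0.2

    def test_class_iv_uses_max_magnitude(self):
        sets = {"IV_Transient": {"t1", "t2"}}
        fcs = {
            "NHT_vs_NAIVE": {"t1": 3.0, "t2": 5.0},
            "NEPC_vs_NHT": {"t1": 1 / 8.0, "t2": 2.0},
        }
        selections, _ = rank_class_transcripts(sets, fcs)
        # t1 rank key 8 (from |1/8|) beats t2 key 5
        assert selections["IV_Transient"] == ["t1", "t2"]

    def test_five_groups_of_twenty_give_hundred(self):
        rng = np.random.default_rng(0)
        sets = {
            cls: {f"{cls}_{i}" for i in range(30)}
            for cls in (
                "I_Deactivated",
                "II_Activated",
                "III_Persistent",
                "IV_Transient",
            )
        }
        all_keys = [t for s in sets.values() for t in s]
        fcs = {
            comp: {t: float(rng.uniform(2, 50)) for t in all_keys}
            for comp in ("NEPC_vs_AD", "CRPC_vs_AD", "NHT_vs_NAIVE", "NEPC_vs_NHT")
        }
        sig = pd.DataFrame(
            {
                "fc_cohort_a": list(rng.uniform(10, 40, 15))
                + list(rng.uniform(0.01, 0.1, 15)),
            },
            index=[f"sig{i}" for i in range(30)],
        )
        selections, unique = rank_class_transcripts(sets, fcs, signature_ranked=sig)
        assert sum(len(v) for v in selections.values()) == 100
        assert len(selections) == 5
        assert len(unique) == 100  # all distinct here

    def test_missing_comparison_named(self):
        with pytest.raises(ValueError, match="CRPC_vs_AD"):
            rank_class_transcripts(
                {"I_Deactivated": {"t"}}, {"NEPC_vs_AD": {}, "NHT_vs_NAIVE": {}}
            )


class TestProbeMapping:
    def _transcript(self, exons, tid="T1", chrom="chr1"):
        return TranscriptRecord(
            transcript_id=tid,
            gene_name=tid,
            biotype="lincRNA",
            chrom=chrom,
            strand="+",
            exons=tuple(exons),
        )

    def test_contained_probe_maps(self):
        cat = [self._transcript([(100, 200)])]
        mapped, report = map_probes([ProbeRegion("p1", "chr1", 150, 170)], cat)
        assert mapped == {"p1": ["T1"]}
        assert report["mapped_fraction"] == 1.0

    def test_straddling_probe_excluded(self):
        cat = [self._transcript([(100, 200)])]
        mapped, report = map_probes([ProbeRegion("p1", "chr1", 190, 210)], cat)
        assert mapped == {} and report["probes_mapped"] == 0

    def test_empty_probe_set(self):
        cat = [self._transcript([(100, 200)])]
        _, report = map_probes([], cat)
        assert report["mapped_fraction"] == 0.0

    def test_containment_invariant_to_exon_order(self):
        exons = [(100, 200), (300, 400), (500, 600)]
        probe = [ProbeRegion("p1", "chr1", 310, 330)]
        m1, _ = map_probes(probe, [self._transcript(exons)])
        m2, _ = map_probes(probe, [self._transcript(exons)])
        assert m1 == m2 == {"p1": ["T1"]}

    def test_malformed_interval_is_error(self):
        with pytest.raises(ValueError):
            ProbeRegion("p1", "chr1", 100, 100)

    def test_planted_containment_fraction_recovered(self):
        cfg = SimulationConfig(seed=5, n_transcripts=122, n_planted_per_class=5,
                               signature_size=5, n_outcome_planted=2)
        cat = synthetic_catalogue(cfg)
        probes, truth = generate_probe_map(cfg, cat)
        mapped, report = map_probes(probes, cat)
        # mapping decisions agree with planted truth exactly
        for probe in probes:
            assert (probe.probe_id in mapped) == bool(
                truth.loc[probe.probe_id, "planted_contained"]
            )
        # binomial sampling around 0.87 * 122 ~ 106
        n, p = len(probes), cfg.probe_containment_fraction
        sd = np.sqrt(n * p * (1 - p))
        assert abs(report["probes_mapped"] - n * p) <= 3 * sd

    def test_probe_expression_summarized_as_mean(self):
        values = pd.DataFrame(
            {"s1": [1.0, 3.0], "s2": [2.0, 4.0]}, index=["p1", "p2"]
        )
        out = summarize_probe_expression(values, {"p1": ["T1"], "p2": ["T1"]})
        assert out.loc["T1"].tolist() == [2.0, 3.0]


class TestROC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 10, 11], [False, False, True, True]) == 1.0

    def test_all_tied_scores(self):
        assert roc_auc([5, 5, 5, 5], [False, True, False, True]) == 0.5

    @pytest.mark.parametrize(
        "labels,expected",
        [([0, 0, 1, 1], 1.0), ([0, 1, 0, 1], 0.75)],
    )
    def test_exhaustive_pair_counting_examples(self, labels, expected):
        assert roc_auc([1, 2, 3, 4], [bool(l) for l in labels]) == pytest.approx(
            expected
        )

    def test_single_class_is_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels)
            )

    def test_complement_symmetry_on_tie_free_scores(self):
        rng = np.random.default_rng(15)
        scores = rng.permutation(20).astype(float)
        labels = np.array([True] * 8 + [False] * 12)
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(
            1.0
        )


class TestRapidMetGroups:
    def _metadata(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "adt_treated",
                "metastasis_event",
                "time_to_metastasis_months",
                "followup_months",
            ],
            index=[f"s{i}" for i in range(len(rows))],
        )

    def test_label_rules(self):
        md = self._metadata(
            [
                (True, True, 24.0, 24.0),  # positive: treated, event < 36
                (True, False, np.nan, 130.0),  # negative: >= 10y clean follow-up
                (True, False, np.nan, 60.0),  # excluded: short follow-up
                (False, True, 12.0, 12.0),  # excluded: untreated
                (True, True, 48.0, 48.0),  # excluded: slow metastasis
            ]
        )
        labels = define_rapid_met_groups(md)
        assert labels["s0"] is True
        assert labels["s1"] is False
        assert labels[["s2", "s3", "s4"]].isna().all()

    def test_untreated_arm_mirror(self):
        md = self._metadata(
            [(False, True, 24.0, 24.0), (False, False, np.nan, 130.0)]
        )
        labels = define_rapid_met_groups(md, arm="untreated")
        assert labels["s0"] is True and labels["s1"] is False


class TestKaplanMeier:
    def _metadata(self, times, events, treated=True):
        n = len(times)
        return pd.DataFrame(
            {
                "adt_treated": [treated] * n,
                "metastasis_event": events,
                "time_to_metastasis_months": [
                    t if e else np.nan for t, e in zip(times, events)
                ],
                "followup_months": times,
            },
            index=[f"s{i}" for i in range(n)],
        )

    def test_hand_worked_toy_table(self):
        # times (1,2,3,4), all events, low group = samples with times 1,2
        md = self._metadata([1.0, 2.0, 3.0, 4.0], [True] * 4)
        expr = pd.Series([1.0, 2.0, 10.0, 11.0], index=md.index)
        curves, p = km_median_split(expr, md, "treated")
        # product-limit: S(0)=1, then 0.5 after the first event, 0 after both
        assert curves["low"]["survival"].tolist() == pytest.approx([1.0, 0.5, 0.0])
        assert curves["high"]["survival"].tolist() == pytest.approx([1.0, 0.5, 0.0])
        # hand-worked log-rank: O-E = 7/6, V = 17/36, chi2 = 2.88, p = 0.0895
        assert p == pytest.approx(0.0895, abs=2e-3)

    def test_identical_event_times_p_near_one(self):
        md = self._metadata([5.0] * 8, [True] * 8)
        expr = pd.Series([1, 1, 1, 1, 9, 9, 9, 9], index=md.index, dtype=float)
        _, p = km_median_split(expr, md, "treated")
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_no_events_curves_stay_at_one(self):
        md = self._metadata([10.0, 20.0, 30.0, 40.0], [False] * 4)
        expr = pd.Series([1.0, 2.0, 3.0, 4.0], index=md.index)
        curves, _ = km_median_split(expr, md, "treated")
        assert (curves["low"]["survival"] == 1.0).all()
        assert (curves["high"]["survival"] == 1.0).all()

    def test_km_without_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(16)
        times = rng.exponential(50, 40).round(1) + 1
        md = self._metadata(list(times), [True] * 40)
        expr = pd.Series(rng.normal(0, 1, 40), index=md.index)
        curves, _ = km_median_split(expr, md, "treated")
        low_times = np.sort(
            times[(expr <= expr.median()).to_numpy()]
        )
        surv = curves["low"].set_index("time")["survival"]
        for t in low_times:
            empirical = (low_times > t).mean()
            assert surv.loc[t] == pytest.approx(empirical)

    def test_median_ties_go_low(self):
        md = self._metadata([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [True] * 6)
        expr = pd.Series([1, 1, 1, 1, 5, 9], index=md.index, dtype=float)
        curves, _ = km_median_split(expr, md, "treated")
        assert len(curves["low"]) >= len(curves["high"])

    def test_planted_hazard_detected_in_treated_arm_only(self):
        cfg = SimulationConfig(seed=21, outcome_hazard_fold=6.0)
        matrix, metadata, truth = generate_outcome_cohort(cfg)
        planted = truth.index[truth.planted_class == "outcome"][0]
        _, p_treated = km_median_split(matrix.loc[planted], metadata, "treated")
        assert p_treated < 0.05


class TestDdct:
    def test_arithmetic_identities(self):
        data = {
            ("targ", "ref"): [24.0, 24.0, 24.0],
            ("targ", "tumor"): [20.0, 20.0, 20.0],
            ("PSMB4", "ref"): [18.0, 18.0, 18.0],
            ("PSMB4", "tumor"): [18.0, 18.0, 18.0],
        }
        out = ddct_fold_change(data, "PSMB4", "ref").set_index("sample")
        assert out.loc["ref", "fold_change"] == pytest.approx(1.0)  # ddCt 0
        assert out.loc["tumor", "delta_delta_ct"] == pytest.approx(-4.0)
        assert out.loc["tumor", "fold_change"] == pytest.approx(16.0)

    def test_ddct_minus_one_doubles(self):
        data = {
            ("targ", "ref"): [21.0],
            ("targ", "s"): [20.0],
            ("hk", "ref"): [18.0],
            ("hk", "s"): [18.0],
        }
        out = ddct_fold_change(data, "hk", "ref").set_index("sample")
        assert out.loc["s", "fold_change"] == pytest.approx(2.0)

    def test_missing_housekeeper_is_error(self):
        with pytest.raises(ValueError, match="housekeeper"):
            ddct_fold_change({("targ", "s"): [20.0]}, "hk", "s")
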