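import filecmp
import json
import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from precevo.cna import ArmTable
from precevo.subtype import classify_replicates, default_templates, normalize_counts
from precevo.synthetic import (
    CallerProfile,
    ExpressionConfig,
    SimConfig,
    perfect_caller_profiles,
    simulate_clone_tree,
    simulate_cohort,
    simulate_expression,
    simulate_region_calls,
    simulate_segments,
    read_cohort,
    write_cohort,
)
from precevo.trajectory import classify_topology
from precevo.variants import consensus_calls


class TestSimConfig:
    def test_defaults_valid(self):
        SimConfig()

    def test_topology_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(topology_mix=(("linear", 0.5), ("branched", 0.2)))

    def test_depth_positive(self):
        with pytest.raises(ValueError, match="depth"):
            SimConfig(mean_depth=0)

    def test_probability_bounds(self):
        bad = CallerProfile("M2", ((1.0, 1.5),), 0.0)
        with pytest.raises(ValueError):
            SimConfig(caller_profiles=(("M2", bad),))


class TestSimulateCloneTree:
    def test_smallest_linear_case(self):
        tree = simulate_clone_tree(2, "linear", seed=1)
        assert tree.clones["C1"].parent == "root"
        assert tree.clones["C2"].parent == "C1"
        assert tree.dominant("LG") == "C1"
        assert tree.dominant("HG") == "C2"

    def test_smallest_branched_case(self):
        tree = simulate_clone_tree(3, "branched", seed=1)
        assert tree.clones["C2"].parent == "C1"
        assert tree.clones["C3"].parent == "C1"
        assert tree.dominant("LG") == "C2"
        assert tree.dominant("HG") == "C3"

    def test_self_consistency_with_classifier(self):
        grades = {"LG": "LG", "HG": "HG"}
        tree = simulate_clone_tree(4, "linear", seed=7)
        assert classify_topology(tree, grades) == "linear"

    @pytest.mark.parametrize("topology", ["linear", "branched"])
    @pytest.mark.parametrize("seed", range(10))
    def test_all_generated_trees_classify_as_requested(self, topology, seed):
        n = 3 if topology == "branched" else 2
        tree = simulate_clone_tree(n + seed % 2, topology, seed=seed)
        assert classify_topology(tree, {"LG": "LG", "HG": "HG"}) == topology

    def test_mutation_nesting(self):
        tree = simulate_clone_tree(4, "linear", seed=3)
        for cid, clone in tree.clones.items():
            if clone.parent is not None:
                assert clone.muts > tree.clones[clone.parent].muts

    def test_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_clone_tree(1, "linear", seed=0)


@pytest.fixture(scope="module")
def tiny_patient():
    cfg = SimConfig.noiseless(n_patients=1, seed=3)
    return simulate_cohort(cfg).patients[0], cfg


class TestSimulateRegionCalls:
    def test_noiseless_limit_all_callers_identical_to_truth(self, tiny_patient):
        patient, _ = tiny_patient
        region = patient.regions[0]
        calls = simulate_region_calls(
            patient, region.region, perfect_caller_profiles(), seed=1,
            vaf_noise=False, depth_noise=False,
        )
        truth = {tv.key for tv in region.true_variants}
        for caller, vs in calls.items():
            assert {v.key for v in vs} == truth

    def test_unknown_region(self, tiny_patient):
        patient, _ = tiny_patient
        with pytest.raises(KeyError, match="unknown region"):
            simulate_region_calls(patient, "nope", perfect_caller_profiles(), seed=1)

    def test_zero_sensitivity_caller_only_fps(self, tiny_patient):
        patient, _ = tiny_patient
        profiles = {
            "M2": CallerProfile("M2", ((1.0, 1.0),), 0.0),
            "SC": CallerProfile("SC", ((1.0, 1.0),), 0.0),
            "MU": CallerProfile("MU", ((1.0, 0.0),), 0.5),
        }
        calls = simulate_region_calls(patient, patient.regions[0].region, profiles, seed=2)
        truth = {tv.key for tv in patient.regions[0].true_variants}
        assert all(v.key not in truth for v in calls["MU"])

    def test_truncal_vaf_within_binomial_interval(self):
        """Truncal hotspot at clone fraction 1, purity p: VAF ~ Binom(400, p/2)."""
        cfg = SimConfig(n_patients=1, seed=9)
        cohort = simulate_cohort(cfg)
        patient = cohort.patients[0]
        checked = 0
        for region in patient.regions:
            if region.purity == 0:
                continue
            expected = region.purity / 2
            lo = sps.binom.ppf(0.005, 400, expected)
            hi = sps.binom.ppf(0.995, 400, expected)
            hotspots = [tv for tv in region.true_variants if tv.hotspot]
            for caller, calls in region.caller_calls.items():
                for v in calls:
                    if (v.chrom, v.pos, v.ref, v.alt) in {tv.key for tv in hotspots}:
                        assert lo - 1 <= v.tumor_alt * 400 / v.tumor_depth <= hi + 1
                        checked += 1
        assert checked > 0


class TestSimulateSegments:
    def test_1q_gain_yields_ai_and_positive_logr(self, tiny_patient):
        patient, _ = tiny_patient
        arms = ArmTable.toy()
        region = next(r for r in patient.regions if r.grade == "HG")
        gains = [e for e in region.true_events if e.direction == "gain"]
        ai, logr = simulate_segments(patient, region.region, seed=4, noise_sd=0.0)
        for g in gains:
            assert any(s.chrom == g.chrom and s.start == g.start and s.end == g.end for s in ai)
            piece = next(
                s for s in logr if s.chrom == g.chrom and s.start == g.start
            )
            assert piece.value > 0

    def test_no_cnas_all_neutral(self, tiny_patient):
        patient, _ = tiny_patient
        nd = next((r for r in patient.regions if r.grade in ("ND", "AC")), None)
        if nd is None:
            pytest.skip("no non-neoplastic region in this draw")
        ai, logr = simulate_segments(patient, nd.region, seed=0, noise_sd=0.0)
        assert ai == []
        assert all(abs(s.value) < 1e-9 for s in logr)

    def test_cnloh_logr_near_zero(self, tiny_patient):
        patient, _ = tiny_patient
        from precevo.cna import overlay_cna

        for region in patient.regions:
            cnlohs = [e for e in region.true_events if e.direction == "cnloh"]
            if not cnlohs:
                continue
            ai, logr = simulate_segments(patient, region.region, seed=1, noise_sd=0.02)
            events = overlay_cna(ai, logr)
            for c in cnlohs:
                match = next(e for e in events if e.start == c.start and e.chrom == c.chrom)
                assert match.direction == "cnloh"


class TestSimulateExpression:
    def test_noiseless_equals_centroid(self):
        cfg = SimConfig.noiseless()
        templates = default_templates()
        frame = simulate_expression("classical", templates, cfg, seed=0, n_replicates=2)
        moffitt = templates["moffitt"]
        expected = np.round(2 ** moffitt.weights["classical"] - 1).astype(int)
        got = frame.loc[moffitt.genes]
        for col in got.columns:
            assert (got[col] == expected.loc[got.index]).all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown template class"):
            simulate_expression("mystery", default_templates(), SimConfig(), seed=0)

    def test_classifiable_recovery_rate(self):
        """Default-noise classical replicates classify correctly in >= 95% of seeds."""
        cfg = SimConfig()
        templates = default_templates()
        moffitt = templates["moffitt"]
        ok = 0
        n = 100
        frames = [
            simulate_expression("classical", templates, cfg, seed=s, n_replicates=1,
                                region_id=f"r{s}")
            for s in range(n)
        ]
        mat = normalize_counts(pd.concat(frames, axis=1))
        calls = classify_replicates(mat, moffitt, n_perm=200, seed=0)
        for c in calls:
            ok += c.classifiable and c.label == "classical" and c.fdr < 0.05
        assert ok >= 0.95 * n

    def test_nonclassifiable_source(self):
        """Flat sources come out nonclassifiable in >= 90% of seeds."""
        cfg = SimConfig()
        templates = default_templates()
        moffitt = templates["moffitt"]
        frames = [
            simulate_expression("none", templates, cfg, seed=s, n_replicates=1,
                                region_id=f"r{s}")
            for s in range(100)
        ]
        mat = normalize_counts(pd.concat(frames, axis=1))
        calls = classify_replicates(mat, moffitt, n_perm=200, seed=0)
        n_null = sum(1 for c in calls if not c.classifiable)
        assert n_null >= 90


class TestWriteCohort:
    def test_round_trip_exact(self, noiseless_cohort, noiseless_cohort_dir):
        cohort2 = read_cohort(noiseless_cohort_dir)
        assert cohort2.config == noiseless_cohort.config
        for p1, p2 in zip(noiseless_cohort.patients, cohort2.patients):
            assert p1.tree.to_dict() == p2.tree.to_dict()
            assert p1.topology == p2.topology
            for r1, r2 in zip(p1.regions, p2.regions):
                assert (r1.region, r1.grade, r1.purity) == (r2.region, r2.grade, r2.purity)
                for caller in r1.caller_calls:
                    assert sorted(r1.caller_calls[caller], key=lambda v: v.key) == sorted(
                        r2.caller_calls[caller], key=lambda v: v.key
                    )
                assert sorted(r1.ai_segments) == sorted(r2.ai_segments)
                assert sorted(r1.logr_segments) == sorted(r2.logr_segments)
                assert {tv.key for tv in r1.true_variants} == {
                    tv.key for tv in r2.true_variants
                }
        assert noiseless_cohort.expression.equals(
            cohort2.expression.loc[noiseless_cohort.expression.index,
                                   noiseless_cohort.expression.columns]
        )

    def test_manifest_lists_three_vcfs_per_region(self, tmp_path):
        cfg = SimConfig(n_patients=4, mu_missing_prob=0.0, seed=2)
        manifest = write_cohort(simulate_cohort(cfg), tmp_path)
        assert len(manifest["patients"]) == 4
        for pspec in manifest["patients"]:
            for rspec in pspec["regions"]:
                assert sorted(rspec["vcfs"]) == ["M2", "MU", "SC"]

    def test_empty_cohort(self, tmp_path):
        cfg = SimConfig(n_patients=0, seed=0)
        cohort = simulate_cohort(cfg)
        manifest = write_cohort(cohort, tmp_path)
        assert manifest["patients"] == []
        assert (tmp_path / "manifest.json").exists()

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_patients=2, seed=77)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_cohort(simulate_cohort(cfg), d1)
        write_cohort(simulate_cohort(cfg), d2)
        for root, _, files in os.walk(d1):
            rel = os.path.relpath(root, d1)
            for f in files:
                p1 = os.path.join(root, f)
                p2 = os.path.join(d2, rel, f)
                assert filecmp.cmp(p1, p2, shallow=False), f"{rel}/{f} differs"


def test_consensus_recall_monotone_in_sensitivity():
    """Raising every caller's sensitivity never lowers consensus recall (20 seeds)."""
    def recall_at(s_lo, seed):
        profiles = {
            c: CallerProfile(c, ((1.0, s_lo),), 0.0) for c in ("M2", "SC", "MU")
        }
        cfg = SimConfig(n_patients=1, seed=seed, vaf_noise=False, depth_noise=False,
                        caller_profiles=tuple(sorted(profiles.items())),
                        mu_missing_prob=0.0)
        cohort = simulate_cohort(cfg)
        hits = total = 0
        for p in cohort.patients:
            for r in p.regions:
                truth = {tv.key for tv in r.true_variants}
                if not truth:
                    continue
                cons = {v.key for v in consensus_calls(r.caller_calls, ["M2", "SC", "MU"])}
                hits += len(cons & truth)
                total += len(truth)
        return hits / total if total else 1.0

    for seed in range(20):
        r_low = recall_at(0.5, seed)
        r_high = recall_at(0.95, seed)
        assert r_high >= r_low - 1e-9
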