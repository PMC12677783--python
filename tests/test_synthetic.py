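"""synthetic_cohort: schedules, planted networks, oscillatory recordings,
cohort-level group effects."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import normalized_mutual_info_score as nmi

from conftest import FAST_PIPELINE
from netreconfig.connectivity import build_multilayer
from netreconfig.dynamic_communities import louvain_partition, temporal_consensus
from netreconfig.pipeline import analyze_cohort
from netreconfig.signal_io import band_window
from netreconfig.synthetic import (CohortSpec, CommunitySchedule, GroupEffect,
                                   generate_cohort, generate_planted_multilayer,
                                   generate_recording, random_schedule,
                                   write_cohort)


def simple_schedule(n_nodes=6, switch=True):
    lab1 = np.array([1] * (n_nodes // 2) + [2] * (n_nodes - n_nodes // 2))
    if not switch:
        return CommunitySchedule(n_nodes=n_nodes, epochs=[(1, 6, lab1)])
    lab2 = lab1.copy()
    lab2[: max(2, n_nodes // 4)] = 2
    return CommunitySchedule(n_nodes=n_nodes,
                             epochs=[(1, 3, lab1), (4, 6, lab2)])


class TestCommunitySchedule:
    def test_epochs_must_tile(self):
        lab = np.ones(4, dtype=int)
        with pytest.raises(ValueError, match="tile"):
            CommunitySchedule(n_nodes=4, epochs=[(1, 3, lab), (5, 6, lab)])

    def test_label_length_checked(self):
        with pytest.raises(ValueError, match="label"):
            CommunitySchedule(n_nodes=4, epochs=[(1, 3, np.ones(3, int))])

    def test_expand_shape_and_content(self):
        sched = simple_schedule()
        mat = sched.expand()
        assert mat.shape == (6, 6)
        np.testing.assert_array_equal(mat[:, 0], sched.epochs[0][2])
        np.testing.assert_array_equal(mat[:, 5], sched.epochs[1][2])

    def test_random_schedule_changes_between_epochs(self):
        sched = random_schedule(n_nodes=12, n_layers=9, n_epochs=3,
                                n_communities=3, seed=0)
        mat = sched.expand()
        assert not np.array_equal(mat[:, 2], mat[:, 3])
        assert not np.array_equal(mat[:, 5], mat[:, 6])


class TestPlantedMultilayer:
    def test_deterministic_clique_limit(self):
        sched = simple_schedule()
        net, seq = generate_planted_multilayer(sched, p_in=1.0, p_out=0.0,
                                               weight_in=1.0, weight_out=0.0,
                                               n_layers=6, seed=0)
        for t in range(6):
            part = seq.labels[:, t]
            same = part[:, None] == part[None, :]
            expected = np.where(same, 1.0, 0.0)
            np.fill_diagonal(expected, 0.0)
            np.testing.assert_array_equal(net.layers[t], expected)

    def test_same_seed_identical(self):
        sched = simple_schedule()
        net1, _ = generate_planted_multilayer(sched, 0.8, 0.1, 1.0, 0.4, 6,
                                              seed=5)
        net2, _ = generate_planted_multilayer(sched, 0.8, 0.1, 1.0, 0.4, 6,
                                              seed=5)
        np.testing.assert_array_equal(net1.layers, net2.layers)

    def test_layer_count_mismatch(self):
        with pytest.raises(ValueError, match="layers"):
            generate_planted_multilayer(simple_schedule(), 0.8, 0.1, 1.0, 0.4,
                                        n_layers=7, seed=0)

    def test_probability_ordering_enforced(self):
        with pytest.raises(ValueError, match="p_out"):
            generate_planted_multilayer(simple_schedule(), 0.5, 0.6, 1.0, 0.4,
                                        n_layers=6, seed=0)

    def test_louvain_recovers_planted_partition(self):
        lab = np.array([1] * 10 + [2] * 10)
        sched = CommunitySchedule(n_nodes=20, epochs=[(1, 10, lab)])
        net, seq = generate_planted_multilayer(sched, p_in=0.9, p_out=0.05,
                                               weight_in=1.0, weight_out=0.5,
                                               n_layers=10, seed=3)
        perfect = sum(
            nmi(louvain_partition(net.layers[t], seed=t), seq.labels[:, t])
            == pytest.approx(1.0)
            for t in range(10)
        )
        assert perfect >= 9


class TestGenerateRecording:
    def _spec(self, **kw):
        defaults = dict(
            n_subjects_per_group=2,
            group_effects={"control": GroupEffect(1.0),
                           "patient": GroupEffect(0.5)},
            sampling_rate=500.0, duration=12.0, seed=0,
        )
        defaults.update(kw)
        return CohortSpec(**defaults)

    def test_sample_count(self):
        spec = self._spec(duration=60.0)
        sched = random_schedule(n_nodes=19, n_layers=30, seed=0)
        rec = generate_recording(sched, spec, "s", "control")
        assert rec.n_samples == 30000
        assert rec.n_channels == 19

    def test_noiseless_within_community_plv(self):
        spec = self._spec(noise_sd=0.0, bands={"alpha": (8.0, 13.0)})
        sched = simple_schedule(n_nodes=6, switch=False)
        rec = generate_recording(sched, spec, "s", "control",
                                 rng=np.random.default_rng(1))
        bws = band_window(rec, bands=spec.bands)
        net = build_multilayer(bws, "alpha")
        part = sched.epochs[0][2]
        for t in range(net.n_layers):
            for i in range(6):
                for j in range(i + 1, 6):
                    if part[i] == part[j]:
                        assert net.layers[t, i, j] >= 0.999

    def test_between_community_plv_much_lower(self):
        spec = self._spec(noise_sd=0.5, bands={"alpha": (8.0, 13.0)},
                          duration=20.0)
        sched = simple_schedule(n_nodes=8, switch=False)
        rec = generate_recording(sched, spec, "s", "control",
                                 rng=np.random.default_rng(2))
        net = build_multilayer(band_window(rec, bands=spec.bands), "alpha")
        part = sched.epochs[0][2]
        iu = np.triu_indices(8, 1)
        same = part[iu[0]] == part[iu[1]]
        within = net.layers[:, iu[0], iu[1]][:, same].mean()
        between = net.layers[:, iu[0], iu[1]][:, ~same].mean()
        assert within / between > 3

    def test_bad_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            self._spec(bands={"hf": (100.0, 300.0)})

    def test_unknown_group_rejected(self):
        spec = self._spec()
        with pytest.raises(ValueError, match="group"):
            generate_recording(simple_schedule(), spec, "s", "nope")

    def test_reproducible(self):
        spec = self._spec()
        sched = simple_schedule(n_nodes=19)
        r1 = generate_recording(sched, spec, "s", "control",
                                rng=np.random.default_rng(7))
        r2 = generate_recording(sched, spec, "s", "control",
                                rng=np.random.default_rng(7))
        np.testing.assert_array_equal(r1.samples, r2.samples)


class TestPipelineRecoverability:
    def test_low_noise_recording_recovers_schedule(self):
        # coupling 1.0, noise_sd <= 0.2 x amplitude: NMI >= 0.9 per layer
        spec = CohortSpec(
            n_subjects_per_group=2,
            group_effects={"a": GroupEffect(1.0), "b": GroupEffect(1.0)},
            duration=20.0, noise_sd=0.2, amplitude=1.0,
            bands={"alpha": (8.0, 13.0)}, seed=0,
        )
        sched = random_schedule(n_nodes=19, n_layers=10, n_epochs=2,
                                n_communities=3, seed=4)
        rec = generate_recording(sched, spec, "s", "a",
                                 rng=np.random.default_rng(11))
        net = build_multilayer(band_window(rec, bands=spec.bands), "alpha")
        seq = temporal_consensus(net, omega=1.0, n_init=10, seed=12)
        truth = sched.expand()
        for t in range(10):
            assert nmi(seq.labels[:, t], truth[:, t]) >= 0.9


class TestGenerateCohort:
    def test_counts_and_labels(self):
        spec = CohortSpec(
            n_subjects_per_group=20,
            group_effects={"control": GroupEffect(1.0),
                           "patient": GroupEffect(0.5)},
            duration=4.0, seed=1,
        )
        sched = random_schedule(n_nodes=19, n_layers=2, n_epochs=2, seed=2)
        cohort = generate_cohort(spec, sched)
        assert len(cohort) == 40
        groups = [g for _r, g in cohort]
        assert groups.count("control") == 20
        assert groups.count("patient") == 20

    def test_requires_two_groups(self):
        spec = CohortSpec(n_subjects_per_group=3,
                          group_effects={"only": GroupEffect(1.0)},
                          duration=4.0)
        with pytest.raises(ValueError, match="2 groups"):
            generate_cohort(spec, random_schedule(n_layers=2, n_epochs=2,
                                                  seed=0))

    def test_deterministic_under_seed(self):
        spec = CohortSpec(
            n_subjects_per_group=2,
            group_effects={"a": GroupEffect(1.0), "b": GroupEffect(0.5)},
            duration=4.0, seed=9,
        )
        sched = random_schedule(n_layers=2, n_epochs=2, seed=3)
        c1 = generate_cohort(spec, sched)
        c2 = generate_cohort(spec, sched)
        for (r1, _), (r2, _) in zip(c1, c2):
            np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_write_cohort_outputs(self, tmp_path):
        spec = CohortSpec(
            n_subjects_per_group=2,
            group_effects={"a": GroupEffect(1.0), "b": GroupEffect(0.5)},
            duration=4.0, seed=9,
        )
        sched = random_schedule(n_layers=2, n_epochs=2, seed=3)
        cohort = generate_cohort(spec, sched)
        manifest = write_cohort(cohort, sched, tmp_path, seed=9)
        assert manifest.exists()
        assert (tmp_path / "ground_truth_partitions.tsv").exists()
        assert len(list(tmp_path.glob("*.tsv"))) >= 5


class TestGroupEffects:
    def test_planted_deficit_lowers_patient_cohesion(self, cohort_run):
        table = cohort_run["table"]
        cs = (table[table.metric == "cohesion_strength"]
              .groupby("group")["value"].mean())
        assert cs["patient"] < cs["control"]

    def test_equal_multipliers_null_calibrated(self):
        # equal coupling in both groups: Mann-Whitney on downstream
        # cohesion strength non-significant at alpha=0.05 in >= 90% of
        # 20 seeded repetitions (scaled-down pipeline for runtime)
        sched = random_schedule(n_nodes=19, n_layers=6, n_epochs=3,
                                n_communities=3, seed=30)
        non_sig = 0
        for rep in range(20):
            spec = CohortSpec(
                n_subjects_per_group=4,
                group_effects={"a": GroupEffect(1.0), "b": GroupEffect(1.0)},
                duration=12.0, bands={"alpha": (8.0, 13.0)}, seed=100 + rep,
            )
            cohort = generate_cohort(spec, sched)
            table = analyze_cohort(cohort, seed=200 + rep,
                                   bands=spec.bands, **FAST_PIPELINE)
            subj = (table[table.metric == "cohesion_strength"]
                    .groupby(["subject_id", "group"])["value"].mean()
                    .reset_index())
            a = subj[subj.group == "a"]["value"]
            b = subj[subj.group == "b"]["value"]
            p = mannwhitneyu(a, b, alternative="two-sided").pvalue
            non_sig += p >= 0.05
        assert non_sig >= 18

    def test_coupling_monotonicity(self):
        # lower coupling multiplier never increases mean cohesion strength
        sched = random_schedule(n_nodes=19, n_layers=10, n_epochs=4,
                                n_communities=3, seed=40)
        means = []
        for coupling in (1.0, 0.7, 0.4):
            spec = CohortSpec(
                n_subjects_per_group=4,
                group_effects={"ref": GroupEffect(1.0),
                               "grp": GroupEffect(coupling)},
                duration=20.0, bands={"alpha": (8.0, 13.0),
                                      "beta": (13.0, 30.0)}, seed=41,
            )
            cohort = [sg for sg in generate_cohort(spec, sched)
                      if sg[1] == "grp"]
            table = analyze_cohort(cohort, seed=42, bands=spec.bands,
                                   **FAST_PIPELINE)
            means.append(table[table.metric == "cohesion_strength"]
                         ["value"].mean())
        assert means[0] >= means[1] >= means[2]
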