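import numpy as np
import pandas as pd
import pytest

from nucleodyn import simulate as sim


def _one_gene_frame(start=100_000, end=200_000, strand="+"):
    return pd.DataFrame(
        [{
            "chrom": "chr1", "start": start, "end": end, "name": "g1", "score": 0,
            "strand": strand,
            "tss": start if strand == "+" else end - 1,
            "tts": end - 1 if strand == "+" else start,
        }]
    )


class TestLandscape:
    SPEC = sim.LandscapeSpec(genome_length=1_000_000, seed=3)

    def test_phased_array_periodicity(self):
        track = sim.simulate_landscape(self.SPEC, _one_gene_frame())["chr1"]
        body = track[100_000:200_000] - track[100_000:200_000].mean()
        ac = np.correlate(body, body, mode="full")[len(body) - 1 :]
        lag = 150 + np.argmax(ac[150:250])
        assert abs(lag - self.SPEC.nrl) <= 5

    def test_empty_gene_set_homogeneous(self):
        track = sim.simulate_landscape(self.SPEC, None)["chr1"]
        bins = track.reshape(-1, 1_000).mean(axis=1)
        assert bins.std() / bins.mean() < 0.01

    def test_deterministic(self):
        t1 = sim.simulate_landscape(self.SPEC, _one_gene_frame())["chr1"]
        t2 = sim.simulate_landscape(self.SPEC, _one_gene_frame())["chr1"]
        assert np.array_equal(t1, t2)

    def test_gene_outside_genome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_landscape(self.SPEC, _one_gene_frame(end=2_000_000))

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            sim.LandscapeSpec(genome_length=1_000)  # < 10 * nrl
        with pytest.raises(ValueError):
            sim.LandscapeSpec(frag_len_sd=-1)


class TestApplyEvents:
    def _flat(self, length=100_000):
        return {"chr1": np.full(length, 1.0 / 190)}

    def test_depletion_halves_mean_exactly(self):
        track = self._flat()
        ev = sim.PlantedEvent("depletion", "chr1", 0, 25_000, factor=0.5)
        out = sim.apply_events(track, [ev])
        assert out["chr1"][:25_000].mean() == pytest.approx(track["chr1"][:25_000].mean() / 2)
        assert np.array_equal(out["chr1"][25_000:], track["chr1"][25_000:])

    def test_empty_event_list_identity(self):
        track = self._flat()
        out = sim.apply_events(track, [])
        assert np.array_equal(out["chr1"], track["chr1"])

    def test_overlapping_events_rejected(self):
        evs = [
            sim.PlantedEvent("depletion", "chr1", 0, 30_000, factor=0.5),
            sim.PlantedEvent("enrichment", "chr1", 20_000, 50_000, factor=2.0),
        ]
        with pytest.raises(ValueError, match="contradictory"):
            sim.apply_events(self._flat(), evs)

    def test_shift_moves_peaks_by_stated_lag(self):
        spec = sim.LandscapeSpec(genome_length=500_000, seed=0)
        track = sim.simulate_landscape(spec, _one_gene_frame(100_000, 150_000))
        ev = sim.PlantedEvent("shift", "chr1", 100_000, 150_000, shift_bp=15)
        out = sim.apply_events(track, [ev])
        a = track["chr1"][100_000:150_000]
        b = out["chr1"][100_000:150_000]
        # brute-force cross-correlation over candidate lags
        core = a[100:-100]
        lags = list(range(-40, 41))
        xc = [np.dot(core, b[100 + k : 100 + k + len(core)]) for k in lags]
        assert lags[int(np.argmax(xc))] == 15

    def test_event_validation(self):
        with pytest.raises(ValueError):
            sim.PlantedEvent("depletion", "chr1", 0, 100, factor=1.5)
        with pytest.raises(ValueError):
            sim.PlantedEvent("shift", "chr1", 0, 100, shift_bp=0)
        with pytest.raises(ValueError):
            sim.PlantedEvent("depletion", "chr1", 100, 100, factor=0.5)


class TestSampleFragments:
    def test_poisson_total_count(self):
        track = {"chr1": np.full(2_000_000, 1.0 / 190)}
        mass = track["chr1"].sum()
        occupancy = 100_000 / mass
        frags = sim.sample_fragments(track, occupancy, seed=5)["chr1"]
        assert abs(len(frags) - 100_000) < 4 * np.sqrt(100_000)

    def test_point_mass_midpoints(self):
        track = {"chr1": np.zeros(10_000)}
        track["chr1"][5_000] = 1.0
        frags = sim.sample_fragments(track, 200.0, seed=1)["chr1"]
        assert len(frags) > 0
        assert np.all(np.abs(frags["midpoint"] - 5_000) <= 1)

    def test_same_seed_identical_output(self):
        track = {"chr1": np.full(100_000, 1.0 / 190)}
        f1 = sim.sample_fragments(track, 30.0, seed=9)["chr1"]
        f2 = sim.sample_fragments(track, 30.0, seed=9)["chr1"]
        pd.testing.assert_frame_equal(f1, f2)

    def test_nonpositive_occupancy_rejected(self):
        with pytest.raises(ValueError):
            sim.sample_fragments({"chr1": np.ones(1_000)}, 0.0)

    def test_lengths_clipped(self):
        track = {"chr1": np.full(50_000, 1.0)}
        frags = sim.sample_fragments(track, 0.01, frag_len_sd=80.0, seed=2)["chr1"]
        lengths = frags["end"] - frags["start"]
        assert lengths.min() >= 40  # 50 minus edge clipping slack

    def test_poisson_dispersion_across_regions(self):
        """Counts in disjoint regions behave like independent Poisson draws."""
        track = {"chr1": np.full(1_000_000, 1.0 / 190)}
        occupancy = 60.0 * 190 / 1_000  # expectation 60 per 1-kbp region
        mids = sim.sample_fragments(track, occupancy * (1_000_000 / 190) / track["chr1"].sum(),
                                    seed=13)["chr1"]["midpoint"].to_numpy()
        counts = np.bincount(mids // 5_000, minlength=200)[:200]
        ratio = counts.var() / counts.mean()
        assert 0.8 <= ratio <= 1.2


class TestAnnotations:
    SPEC = sim.LandscapeSpec(genome_length=5_000_000, seed=21)

    def test_all_unexpressed_when_fractions_zero(self):
        truth, genes, counts, peaks = sim.simulate_annotations(
            self.SPEC, n_genes=50, class_fractions={}, seed=1
        )
        assert (truth.gene_classes["gene_class"] == "unexpressed").all()
        assert counts["count_t1"].sum() == 0 and counts["count_t2"].sum() == 0

    def test_class_log2fc_respect_thresholds(self):
        truth, _, counts, _ = sim.simulate_annotations(self.SPEC, n_genes=200, seed=2)
        merged = truth.gene_classes.merge(counts, on="gene")
        up = merged[merged["gene_class"] == "up"]
        down = merged[merged["gene_class"] == "down"]
        const = merged[merged["gene_class"] == "constitutive"]
        assert (np.log2(up["count_t2"] / up["count_t1"]) > 0.6).all()
        assert (np.log2(down["count_t2"] / down["count_t1"]) < -0.6).all()
        assert (const["count_t1"] == const["count_t2"]).all()

    def test_fractions_above_one_rejected(self):
        with pytest.raises(ValueError):
            sim.simulate_annotations(
                self.SPEC, class_fractions={"up": 0.6, "down": 0.6}, seed=0
            )

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="capacity"):
            sim.simulate_annotations(self.SPEC, n_genes=1_000, gene_length=10_000, seed=0)

    def test_inert_regions_avoid_expressed_genes(self):
        truth, genes, _, _ = sim.simulate_annotations(self.SPEC, n_genes=100, seed=3)
        expressed = truth.gene_classes[truth.gene_classes["gene_class"] != "unexpressed"]
        for _, g in expressed.iterrows():
            hit = truth.inert_regions[
                (truth.inert_regions["start"] < g["end"])
                & (truth.inert_regions["end"] > g["start"])
            ]
            assert len(hit) == 0

    def test_truth_lists_every_event_once(self):
        events = [
            sim.PlantedEvent("depletion", "chr1", 1_000_000, 1_025_000, factor=0.5),
            sim.PlantedEvent("shift", "chr1", 2_000_000, 2_010_000, shift_bp=15),
        ]
        truth, _, _, _ = sim.simulate_annotations(self.SPEC, n_genes=30, seed=4, events=events)
        frame = truth.events_frame()
        assert len(frame) == 2
        assert set(frame["kind"]) == {"depletion", "shift"}

    def test_neutral_odds_peak_share_matches_depleted_fraction(self):
        events = [
            sim.PlantedEvent("depletion", "chr1", int(s), int(s) + 100_000, factor=0.5)
            for s in np.arange(0, 5_000_000, 500_000)  # 20% of the genome
        ]
        truth, _, _, peaks = sim.simulate_annotations(
            self.SPEC, n_genes=10, tf_enrichment_odds=1.0, n_peaks=400, seed=5,
            events=events,
        )
        share = peaks["planted_inside"].mean()
        assert abs(share - 0.2) < 4 * np.sqrt(0.2 * 0.8 / 400)

    def test_enriched_odds_peak_share_matches_closed_form(self):
        events = [
            sim.PlantedEvent("depletion", "chr1", int(s), int(s) + 100_000, factor=0.5)
            for s in np.arange(0, 5_000_000, 500_000)
        ]
        truth, _, _, peaks = sim.simulate_annotations(
            self.SPEC, n_genes=10, tf_enrichment_odds=4.0, n_peaks=400, seed=6,
            events=events,
        )
        expected = 4 * 0.2 / (4 * 0.2 + 0.8)  # = 0.5
        share = peaks["planted_inside"].mean()
        assert abs(share - expected) < 4 * np.sqrt(expected * (1 - expected) / 400)


class TestContactsSimulation:
    def test_equal_rates_uniform_positives(self, rng):
        ends = np.sort(rng.choice(1_000_000, 5_000, replace=False))
        targets = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500_000]})
        table = sim.simulate_contacts(int(ends[0]), ends, targets, 0.2, 0.2, seed=7)
        inside = table[table["end_pos"] < 500_000]["reads"] > 0
        outside = table[table["end_pos"] >= 500_000]["reads"] > 0
        assert abs(inside.mean() - outside.mean()) < 0.05

    def test_zero_background_positives_only_in_target(self, rng):
        ends = np.sort(rng.choice(1_000_000, 3_000, replace=False))
        targets = pd.DataFrame({"chrom": ["chr1"], "start": [100_000], "end": [200_000]})
        table = sim.simulate_contacts(int(ends[0]), ends, targets, 0.9, 0.0, seed=8)
        positive = table[table["reads"] > 0]["end_pos"]
        assert ((positive >= 100_000) & (positive < 200_000)).all()

    def test_binomial_positive_count(self, rng):
        ends = np.sort(rng.choice(5_000_000, 10_000, replace=False))
        table = sim.simulate_contacts(
            int(ends[0]), ends, pd.DataFrame(columns=["chrom", "start", "end"]),
            0.05, 0.05, seed=9,
        )
        n_pos = (table["reads"] > 0).sum()
        assert abs(n_pos - 500) < 4 * np.sqrt(10_000 * 0.05 * 0.95)

    def test_viewpoint_must_be_fragment_end(self, rng):
        ends = np.sort(rng.choice(100_000, 100, replace=False))
        bad = int(ends.max()) + 17
        with pytest.raises(ValueError, match="viewpoint"):
            sim.simulate_contacts(bad, ends, pd.DataFrame(columns=["chrom", "start", "end"]),
                                  0.5, 0.1, seed=0)

    def test_invalid_rates(self, rng):
        ends = np.arange(0, 1_000, 10)
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        with pytest.raises(ValueError):
            sim.simulate_contacts(0, ends, empty, 0.1, 0.5, seed=0)  # signal < background
        with pytest.raises(ValueError):
            sim.simulate_contacts(0, ends, empty, 1.5, 0.1, seed=0)


def test_generators_are_bitwise_reproducible(tmp_path):
    """One seed, two full generations, byte-identical files."""
    spec = sim.LandscapeSpec(genome_length=1_000_000, seed=17)
    outputs = []
    for run in range(2):
        truth, genes, counts, peaks = sim.simulate_annotations(spec, n_genes=30, seed=17)
        track = sim.simulate_landscape(spec, genes)
        frags = sim.sample_fragments(track, 5.0, seed=17)["chr1"]
        path = tmp_path / f"run{run}.bed"
        frags.to_csv(path, sep="\t", index=False)
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]
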