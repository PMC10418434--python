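import numpy as np
import pytest

from deepsata.motifs import MotifScanner, reverse_complement
from deepsata.simulate import (
    SimConfig,
    simulate_genome,
    simulate_peaks,
    simulate_second_species,
    simulate_study,
    simulate_variants,
)

SMALL = dict(chrom_lengths={"chr1": 80_000, "chr2": 80_000}, n_variants=60)


@pytest.fixture(scope="module")
def small_study():
    return simulate_study(SimConfig(seed=3, **SMALL))


class TestGenome:
    def test_same_seed_identical_output(self):
        a = simulate_genome(SimConfig(seed=11, **SMALL))
        b = simulate_genome(SimConfig(seed=11, **SMALL))
        assert a.genome == b.genome
        assert a.ground_truth.registry.equals(b.ground_truth.registry)

    def test_realized_gc_close_to_requested(self):
        cfg = SimConfig(seed=11, gc_content=0.40,
                        chrom_lengths={"chr1": 300_000}, n_variants=10)
        study = simulate_genome(cfg)
        seq = study.genome["chr1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.40, abs=0.01)

    def test_every_planted_instance_recovered_by_scanner(self, small_study):
        scanner = MotifScanner(small_study.motifs)
        found = {
            (chrom, mid): {h.start for h in scanner.scan(small_study.genome[chrom], mid)}
            for chrom in small_study.genome
            for mid in small_study.motif_map
        }
        for row in small_study.ground_truth.registry.itertuples():
            assert row.start in found[(row.chrom, row.motif_id)], (
                f"planted {row.motif_id} at {row.chrom}:{row.start} not recovered"
            )

    def test_planted_sequence_matches_consensus(self, small_study):
        row = small_study.ground_truth.registry.iloc[0]
        motif = small_study.motif_map[row["motif_id"]]
        site = small_study.genome[row["chrom"]][row["start"] : row["start"] + len(motif)]
        expected = motif.consensus if row["strand"] == "+" else reverse_complement(motif.consensus)
        assert site == expected

    def test_excess_plant_density_rejected(self):
        cfg = SimConfig(seed=0, chrom_lengths={"chr1": 2_000},
                        plant_rate_per_kb=100.0, n_variants=2)
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(cfg)


class TestPeaks:
    def test_noiseless_peaks_coincide_with_driver_bins(self):
        cfg = SimConfig(seed=5, label_noise=0.0, **SMALL)
        study = simulate_genome(cfg)
        peaks = simulate_peaks(study)
        reg = study.ground_truth.registry
        for tissue, drivers in study.ground_truth.tissue_drivers.items():
            driver_bins = set()
            for row in reg[reg["motif_id"].isin(drivers)].itertuples():
                for b in range(row.start // 200, (row.start + row.length - 1) // 200 + 1):
                    driver_bins.add((row.chrom, b))
            peak_bins = {
                (iv.chrom, b)
                for iv in peaks[tissue]
                for b in range(iv.start // 200, iv.end // 200)
            }
            assert peak_bins <= driver_bins
            # the default peak fraction is generous enough to keep them all
            assert peak_bins == driver_bins

    def test_tissue_overlap_equals_shared_driver_bins(self):
        cfg = SimConfig(seed=5, label_noise=0.0, **SMALL)
        study = simulate_genome(cfg)
        peaks = simulate_peaks(study)
        t1, t2 = study.tissues[:2]

        def bins_of(tissue):
            return {
                (iv.chrom, b)
                for iv in peaks[tissue]
                for b in range(iv.start // 200, iv.end // 200)
            }

        overlap = bins_of(t1) & bins_of(t2)
        reg = study.ground_truth.registry
        d1 = set(study.ground_truth.tissue_drivers[t1])
        d2 = set(study.ground_truth.tissue_drivers[t2])
        both = set()
        for (chrom, b) in overlap:
            rows = reg[(reg["chrom"] == chrom)
                       & (reg["start"] // 200 <= b)
                       & ((reg["start"] + reg["length"] - 1) // 200 >= b)]
            mids = set(rows["motif_id"])
            both.add(((chrom, b), bool(mids & d1) and bool(mids & d2)))
        assert all(flag for _, flag in both)

    def test_label_noise_flips_expected_fraction(self):
        base = SimConfig(seed=9, label_noise=0.0, **SMALL)
        noisy = SimConfig(seed=9, label_noise=0.10, **SMALL)
        s0, s1 = simulate_genome(base), simulate_genome(noisy)
        p0, p1 = simulate_peaks(s0), simulate_peaks(s1)
        tissue = s0.tissues[0]
        n_bins = sum(len(s) // 200 for s in s0.genome.values())

        def membership(peaks):
            m = set()
            for iv in peaks[tissue]:
                for b in range(iv.start // 200, iv.end // 200):
                    m.add((iv.chrom, b))
            return m

        flipped = len(membership(p0) ^ membership(p1))
        assert flipped / n_bins == pytest.approx(0.10, abs=0.02)


class TestVariants:
    def test_class_counts_follow_fraction(self):
        cfg = SimConfig(seed=7, n_variants=200, fraction_regulatory=0.5,
                        chrom_lengths={"chr1": 150_000, "chr2": 150_000})
        study = simulate_study(cfg)
        variants, classes = simulate_variants(study)
        counts = classes["klass"].value_counts()
        assert counts["motif_ablating"] == 100
        assert counts["neutral"] == 100

    def test_ablating_alt_is_least_probable_base(self, small_study):
        variants, classes = simulate_variants(small_study)
        reg = small_study.ground_truth.registry
        abl = classes[classes["klass"] == "motif_ablating"]
        for row in abl.itertuples():
            motif = small_study.motif_map[row.motif_id]
            hit = reg[(reg["chrom"] == row.chrom)
                      & (reg["start"] <= row.pos - 1)
                      & (reg["start"] + reg["length"] > row.pos - 1)].iloc[0]
            offset = (row.pos - 1) - hit["start"]
            col = offset if hit["strand"] == "+" else hit["length"] - 1 - offset
            alt = row.alt if hit["strand"] == "+" else reverse_complement(row.alt)
            probs = motif.ppm[col]
            assert probs["ATCG".index(alt)] <= probs.min() + 1e-9 or (
                # fallback base when the genome base already is the least probable
                probs["ATCG".index(alt)] <= np.sort(probs)[1] + 1e-9
            )

    def test_neutral_variants_far_from_planted_sites(self, small_study):
        variants, classes = simulate_variants(small_study)
        reg = small_study.ground_truth.registry
        neutral = classes[classes["klass"] == "neutral"]
        for row in neutral.itertuples():
            near = reg[(reg["chrom"] == row.chrom)
                       & (reg["start"] - 50 <= row.pos - 1)
                       & (reg["start"] + reg["length"] + 50 > row.pos - 1)]
            assert len(near) == 0

    def test_rescanning_alt_window_loses_ablated_hit(self, small_study):
        scanner = MotifScanner(small_study.motifs)
        variants, classes = simulate_variants(small_study)
        abl = classes[classes["klass"] == "motif_ablating"].head(40)
        reg = small_study.ground_truth.registry
        lost = 0
        for row in abl.itertuples():
            hit = reg[(reg["chrom"] == row.chrom)
                      & (reg["start"] <= row.pos - 1)
                      & (reg["start"] + reg["length"] > row.pos - 1)].iloc[0]
            chrom_seq = small_study.genome[row.chrom]
            w0 = max(0, hit["start"] - 20)
            window = chrom_seq[w0 : hit["start"] + hit["length"] + 20]
            pos_in_window = (row.pos - 1) - w0
            alt_window = window[:pos_in_window] + row.alt + window[pos_in_window + 1 :]
            hit_offset = hit["start"] - w0
            before = {h.start for h in scanner.scan(window, row.motif_id)}
            after = {h.start for h in scanner.scan(alt_window, row.motif_id)}
            assert hit_offset in before
            if hit_offset not in after:
                lost += 1
        assert lost / len(abl) >= 0.9


class TestSecondSpecies:
    def test_shared_drivers_new_genome_same_motifs(self, small_study):
        cfg = SimConfig(seed=3, **SMALL)
        sp2 = simulate_second_species(cfg, small_study, seed=99)
        assert sp2.genome != small_study.genome
        assert [m.id for m in sp2.motifs] == [m.id for m in small_study.motifs]
        assert sp2.ground_truth.tissue_drivers == small_study.ground_truth.tissue_drivers
        np.testing.assert_allclose(sp2.motifs[0].ppm, small_study.motifs[0].ppm)

    def test_unshared_gets_fresh_motif_library(self, small_study):
        cfg = SimConfig(seed=3, **SMALL)
        sp2 = simulate_second_species(cfg, None, seed=99)
        assert not np.allclose(sp2.motifs[0].ppm, small_study.motifs[0].ppm)
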