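"""Planted-profile generator: blend arithmetic, determinism, ground truth."""

import numpy as np
import pytest

from plantdti import (
    compute_base_preference, expand_iupac, sample_catalogue, sample_planted_profiles,
    sample_promoter_with_spikes,
)
from plantdti.constants import BASE_ORDER, IUPAC_CODES
from plantdti.errors import ConfigurationError, InvariantError
from plantdti.synthetic_data import SyntheticConfig, benchmark_config


class TestPlantedProfiles:
    def test_full_strength_columns_one_hot(self):
        profiles = sample_planted_profiles(SyntheticConfig(planting_strength=1.0, seed=0))
        for profile in profiles.values():
            assert np.all(np.sort(profile.matrix, axis=1)[:, -1] == 1.0)

    def test_zero_strength_uniform(self):
        profiles = sample_planted_profiles(SyntheticConfig(planting_strength=0.0, seed=0))
        for profile in profiles.values():
            assert np.allclose(profile.matrix, 0.25)

    def test_half_strength_blend_arithmetic(self):
        profiles = sample_planted_profiles(SyntheticConfig(planting_strength=0.5, seed=0))
        for profile in profiles.values():
            assert np.allclose(np.sort(profile.matrix, axis=1)[:, -1], 0.625)
            assert np.allclose(np.sort(profile.matrix, axis=1)[:, :3], 0.125)

    def test_keyed_by_type_and_length(self):
        config = SyntheticConfig(n_dbd_types=3, lengths=(7, 10))
        profiles = sample_planted_profiles(config)
        assert set(profiles) == {(f"DBD{i:02d}", L) for i in range(3) for L in (7, 10)}

    def test_invalid_config_rejected(self):
        with pytest.raises(InvariantError):
            SyntheticConfig(planting_strength=1.5)
        with pytest.raises(InvariantError):
            SyntheticConfig(n_dbd_types=0)


class TestSampleCatalogue:
    def test_full_strength_sites_identical_and_recoverable(self):
        config = benchmark_config(seed=4, tfs_per_type=5, motifs_per_type=5, lengths=(8,))
        catalogue = sample_catalogue(config)
        positives = catalogue.positives()
        for dbd_type in ("DBD00", "DBD01"):
            group = [p for p in positives if p.dbd_type == dbd_type]
            assert len({p.tfbs_sequence for p in group}) == 1
            estimated = compute_base_preference(group, dbd_type, 8)
            planted = catalogue.profiles[(dbd_type, 8)]
            assert np.allclose(estimated.matrix, planted.matrix)

    def test_catalogue_supports_full_model_grid(self, benchmark):
        lengths = {p.length for p in benchmark.positives}
        types = {p.dbd_type for p in benchmark.positives}
        assert lengths == set(range(7, 16))
        assert len(types) == 2
        for L in lengths:
            for t in types:
                assert any(p.length == L and p.dbd_type == t for p in benchmark.positives)

    def test_same_seed_byte_identical(self):
        config = benchmark_config(seed=12, tfs_per_type=4, motifs_per_type=4, lengths=(7, 9))
        a = sample_catalogue(config).df.to_csv(sep="\t", index=False)
        b = sample_catalogue(config).df.to_csv(sep="\t", index=False)
        assert a == b

    def test_degenerate_motifs_are_valid_iupac_and_contain_source(self):
        config = benchmark_config(seed=6, tfs_per_type=4, motifs_per_type=8,
                                  lengths=(7,), iupac_degeneracy_rate=0.5,
                                  planting_strength=0.7)
        catalogue = sample_catalogue(config)
        degenerate = [r.iupac for r in catalogue.df.itertuples(index=False)
                      if set(r.iupac) - set("ACGT")]
        assert degenerate, "expected some degenerate motifs at rate 0.5"
        for iupac in degenerate:
            assert set(iupac) <= set(IUPAC_CODES)
            # only 2-base codes are used
            assert all(len(IUPAC_CODES[c]) <= 2 for c in iupac)
            assert len(expand_iupac(iupac)) == 2 ** sum(len(IUPAC_CODES[c]) == 2
                                                        for c in iupac)

    def test_dbd_composition_biased_by_type(self):
        from plantdti import encode_dbd

        config = benchmark_config(seed=8, tfs_per_type=30, motifs_per_type=2, lengths=(7,))
        catalogue = sample_catalogue(config)
        comp = {}
        for dbd_type in ("DBD00", "DBD01"):
            seqs = {r.dbd_sequence for r in catalogue.df.itertuples(index=False)
                    if r.dbd_type == dbd_type}
            feats = [encode_dbd(s) for s in seqs]
            comp[dbd_type] = (np.mean([f.hb for f in feats]), np.mean([f.dw for f in feats]))
        # type 0 favours hydrogen-bonding residues, type 1 van-der-Waals
        assert comp["DBD00"][0] > comp["DBD01"][0]
        assert comp["DBD01"][1] > comp["DBD00"][1]


class TestPromoterSpikes:
    CONFIG = benchmark_config(seed=2)

    def test_no_spikes_uniform_background(self):
        seq, truths = sample_promoter_with_spikes(500, [], self.CONFIG, seed=3)
        assert len(seq) == 500
        assert set(seq) <= set(BASE_ORDER)
        assert truths == []

    def test_truth_records_half_open_coordinates(self):
        spikes = [("DBD00", 9, 100, "+"), ("DBD01", 11, 300, "-")]
        seq, truths = sample_promoter_with_spikes(400, spikes, self.CONFIG, seed=3)
        assert [(t.start, t.end, t.strand) for t in truths] == [(100, 109, "+"), (300, 311, "-")]
        fwd_slice = seq[300:311]
        # minus-strand site appears reverse-complemented on the forward strand
        from plantdti import reverse_complement

        assert reverse_complement(fwd_slice) == truths[1].sequence

    def test_full_strength_spike_matches_consensus(self):
        profiles = sample_planted_profiles(self.CONFIG)
        seq, truths = sample_promoter_with_spikes(
            100, [("DBD00", 9, 50, "+")], self.CONFIG, profiles=profiles, seed=3
        )
        consensus = "".join(
            BASE_ORDER[i] for i in profiles[("DBD00", 9)].matrix.argmax(axis=1)
        )
        assert seq[50:59] == consensus

    def test_overlapping_spikes_rejected(self):
        spikes = [("DBD00", 9, 100, "+"), ("DBD01", 9, 105, "+")]
        with pytest.raises(ConfigurationError):
            sample_promoter_with_spikes(400, spikes, self.CONFIG)

    def test_out_of_bounds_spike_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_promoter_with_spikes(100, [("DBD00", 9, 95, "+")], self.CONFIG)

    def test_estimated_profiles_converge_to_planted(self):
        """Sites sampled from a planted profile re-estimate it within 0.05."""
        config = SyntheticConfig(n_dbd_types=1, tfs_per_type=1, motifs_per_type=1,
                                 lengths=(7,), planting_strength=0.6, seed=21)
        profiles = sample_planted_profiles(config)
        profile = profiles[("DBD00", 7)]
        rng = np.random.default_rng(22)
        from plantdti.io_tables import InteractionRecord
        from plantdti.synthetic_data import _draw_site

        recs = [
            InteractionRecord(f"tf{i}", "DBD00", "RKH", _draw_site(profile, rng), label=1)
            for i in range(10_000)
        ]
        estimated = compute_base_preference(recs, "DBD00", 7)
        assert np.max(np.abs(estimated.matrix - profile.matrix)) <= 0.05
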