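"""Coincidence matrices: oracle equivalence, symmetry, anchoring, aux channel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tcstream as tc
from tcstream.coherence import coincidence_columns
from tcstream.cortical import (CorticalTensor, FeatureField,
                               spectral_channel_map)

FR = 125.0


def random_tensor(rng, T=4, D=5, R=3):
    cmap = spectral_channel_map(np.geomspace(200, 2000, D), (2.0,))
    z = rng.standard_normal((T, D, R)) + 1j * rng.standard_normal((T, D, R))
    return CorticalTensor(z, tuple(2.0 ** np.arange(1, R + 1)), cmap, FR)


class TestCoincidenceStack:
    def test_quadrature_pair_yields_identity_block(self):
        cmap = spectral_channel_map(np.array([400.0, 900.0]), (2.0,))
        z = np.array([[1.0 + 0j], [0 + 1j]])[None, :, :]   # D=2, R=1
        ct = CorticalTensor(z, (4.0,), cmap, FR)
        cms = tc.coincidence_stack(ct, 0)
        assert np.allclose(cms.blocks[0], np.eye(2))

    def test_zero_frame_gives_zero_stack(self):
        rng = np.random.default_rng(0)
        ct = random_tensor(rng)
        ct.values[2] = 0
        assert np.all(tc.coincidence_stack(ct, 2).blocks == 0)

    def test_matches_brute_force_outer_product(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            D = rng.integers(2, 7)
            R = rng.integers(1, 4)
            ct = random_tensor(rng, T=3, D=int(D), R=int(R))
            cms = tc.coincidence_stack(ct, 1)
            for r in range(int(R)):
                zr = ct.values[1, :, r]
                expected = np.array(
                    [[np.real(zr[i] * np.conj(zr[j])) for j in range(int(D))]
                     for i in range(int(D))])
                assert np.allclose(cms.blocks[r], expected, atol=1e-12)

    def test_identical_envelopes_give_geometric_mean_cross_term(self):
        cmap = spectral_channel_map(np.array([300.0, 800.0]), (2.0,))
        z0 = 0.7 * np.exp(1j * 0.3)
        z = np.array([[2.0 * z0], [5.0 * z0]])[None, :, :]
        ct = CorticalTensor(z, (4.0,), cmap, FR)
        block = tc.coincidence_stack(ct, 0).blocks[0]
        assert np.isclose(block[0, 1], np.sqrt(block[0, 0] * block[1, 1]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_blocks_symmetric_with_nonnegative_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        ct = random_tensor(rng)
        cms = tc.coincidence_stack(ct, 0)
        for block in cms.blocks:
            assert np.allclose(block, block.T, atol=1e-12)
            assert np.all(np.diag(block) >= 0)

    def test_columns_shortcut_matches_full_stack(self):
        rng = np.random.default_rng(2)
        ct = random_tensor(rng, D=6, R=2)
        idx = np.array([1, 4])
        full = tc.coincidence_stack(ct, 0).stacked[:, idx]
        fast = coincidence_columns(ct, 0, idx)
        assert np.allclose(full, fast, atol=1e-12)

    def test_frame_out_of_range_rejected(self):
        ct = random_tensor(np.random.default_rng(0), T=3)
        with pytest.raises(IndexError):
            tc.coincidence_stack(ct, 7)


class TestTemporalDynamics:
    def test_cmatrix_inherits_rate_filter_inertia(self, cfg):
        """For a stationary stimulus the C-matrix change rate decays after
        the onset transient (the 'inertia' of the coincidence entries)."""
        mix, _ = tc.gen_alternating_tones(400, 1000, reps=8)
        ct = tc.analyze(mix, cfg).tensor
        sel = np.arange(ct.n_channels)
        prev = None
        deltas = []
        for t in range(2, ct.n_frames):       # consecutive frames (8 ms)
            cur = coincidence_columns(ct, t, sel)
            if prev is not None:
                deltas.append(np.linalg.norm(cur - prev)
                              / (np.linalg.norm(prev) + 1e-30))
            prev = cur
        onset = np.mean(deltas[:25])
        steady = np.mean(deltas[-100:])
        # fast-rate blocks keep oscillating with the stimulus cycle, so the
        # decay is bounded but clear
        assert steady < 0.8 * onset

    def test_alternating_vs_synchronous_cross_terms(self, cfg):
        """Anti-phase tones produce near-zero/negative cross-coincidence at
        the dominant rates; synchronous tones produce strongly positive."""
        alt, _ = tc.gen_alternating_tones(400, 1000, tone_dur=0.1,
                                          ioi=0.15, reps=8)
        sync_a, _ = tc.gen_harmonic_complex(400, 1, dur=2.4, amps=[0.4])
        sync_b, _ = tc.gen_harmonic_complex(1000, 1, dur=2.4, amps=[0.4])
        sync = tc.Waveform(sync_a.samples + sync_b.samples)
        sync = tc.gate_bursts(sync, 3.33)
        corr = {}
        for name, w in [("alt", alt), ("sync", sync)]:
            ct = tc.analyze(w, cfg).tensor
            cmap = ct.channel_map
            a = cmap.spectral_near(400, 0.05)[1]
            b = cmap.spectral_near(1000, 0.05)[1]
            z = ct.values[ct.n_frames // 2]
            r = 1  # 4 Hz, the alternation rate regime
            caa = np.real(z[a, r] * np.conj(z[a, r]))
            cbb = np.real(z[b, r] * np.conj(z[b, r]))
            corr[name] = np.real(z[a, r] * np.conj(z[b, r])) / np.sqrt(
                caa * cbb + 1e-30)
        assert corr["alt"] < 0.0
        assert corr["sync"] > 0.5


class TestAnchors:
    def test_pitch_range_selects_only_grid_columns(self, cfg_pitch):
        mix, _ = tc.gen_alternating_complexes(500, 630, reps=2)
        ct = tc.analyze(mix, cfg_pitch).tensor
        anchor = tc.AnchorSpec("pitch_range", pitch_range=(450, 550))
        idx = anchor.resolve(ct.channel_map)
        hz = ct.channel_map.pitch_hz[idx]
        assert np.all((hz >= 450) & (hz <= 550))
        grid = np.asarray(cfg_pitch.pitch.grid())
        expected = ((grid >= 450) & (grid <= 550)).sum()
        assert idx.size == expected

    def test_mode_all_returns_every_column(self, cfg):
        mix, _ = tc.gen_alternating_tones(400, 1000, reps=2)
        ct = tc.analyze(mix, cfg).tensor
        cms = tc.coincidence_stack(ct, 10)
        cols, idx = tc.select_columns(cms, tc.AnchorSpec("all"),
                                      ct.channel_map)
        assert cols.shape == (ct.n_rates * ct.n_channels, ct.n_channels)

    def test_single_channel_selection_matches_block_rows(self, cfg):
        rng = np.random.default_rng(3)
        ct = random_tensor(rng, D=5, R=2)
        cms = tc.coincidence_stack(ct, 0)
        cols, _ = tc.select_columns(
            cms, tc.AnchorSpec("channel_set", channels=[2]), ct.channel_map)
        # symmetry: column j equals row j of each block
        expected = np.concatenate([cms.blocks[r][2] for r in range(2)])
        assert np.allclose(cols[:, 0], expected)

    def test_empty_selection_rejected_with_report(self, cfg):
        mix, _ = tc.gen_alternating_tones(400, 1000, reps=2)
        ct = tc.analyze(mix, cfg).tensor     # pitch disabled -> no pitch cols
        anchor = tc.AnchorSpec("pitch_range", pitch_range=(450, 550))
        with pytest.raises(ValueError, match="selected no columns"):
            anchor.resolve(ct.channel_map)

    def test_parse_anchor_text(self):
        a = tc.AnchorSpec.parse("pitch:450-550")
        assert a.mode == "pitch_range" and a.pitch_range == (450.0, 550.0)
        assert tc.AnchorSpec.parse("channels:3,5").channels == [3, 5]
        assert tc.AnchorSpec.parse(None).mode == "all"
        assert tc.AnchorSpec.parse("aux").mode == "aux"


class TestAuxChannel:
    def test_aux_column_identifies_co_modulated_source(self, cfg):
        pairs = tc.gen_benchmark_pairs(2, dur=2.0, seed=5)
        wa, wb, info = pairs[1]              # disjoint tone pair
        mix, truth = tc.gen_mixture(wa, wb, 0.0)
        ana = tc.analyze(mix, cfg)
        aux = tc.gen_aux_envelope(truth.components[0], cutoff=8.0)
        aux = aux[: ana.tensor.n_frames]
        ct = tc.augment_with_aux(ana.tensor, aux, cfg)
        cmap = ct.channel_map
        aux_idx = cmap.aux_indices()
        assert ct.n_channels == ana.tensor.n_channels + 1
        # average aux coincidence column over steady frames
        col = np.zeros(ct.n_rates * ct.n_channels)
        for t in range(60, ct.n_frames, 4):
            col += coincidence_columns(ct, t, aux_idx)[:, 0]
        col = col.reshape(ct.n_rates, ct.n_channels).sum(axis=0)
        # channels owned by each source (from clean component analyses)
        e = [np.abs(tc.analyze(c, cfg).tensor.values).sum(axis=(0, 2))
             for c in truth.components]
        own0 = e[0] > 3 * e[1]
        own1 = e[1] > 3 * e[0]
        labeled = own0 | own1
        predicted_own0 = col[: ana.tensor.n_channels] > 0
        acc = np.mean(predicted_own0[labeled] == own0[labeled])
        assert acc > 0.9

    def test_constant_aux_gives_near_zero_column(self, cfg):
        # steady state must outlast the 2-Hz kernel (~1.3 s) before checking
        mix, _ = tc.gen_alternating_tones(400, 1000, reps=8)
        ana = tc.analyze(mix, cfg)
        ct = tc.augment_with_aux(ana.tensor, np.ones(ana.tensor.n_frames), cfg)
        aux_idx = ct.channel_map.aux_indices()
        col = coincidence_columns(ct, ct.n_frames - 5, aux_idx)
        scale = np.abs(ct.values[ct.n_frames - 5]).max() ** 2
        assert np.abs(col).max() < 1e-6 * scale

    def test_mixture_envelope_correlates_with_both_sources(self, cfg):
        pairs = tc.gen_benchmark_pairs(2, dur=2.0, seed=5)
        wa, wb, _ = pairs[1]
        mix, truth = tc.gen_mixture(wa, wb, 0.0)
        ana = tc.analyze(mix, cfg)
        aux = tc.gen_aux_envelope(mix, cutoff=8.0)[: ana.tensor.n_frames]
        ct = tc.augment_with_aux(ana.tensor, aux, cfg)
        aux_idx = ct.channel_map.aux_indices()
        col = np.zeros(ct.n_rates * ct.n_channels)
        for t in range(60, ct.n_frames, 4):
            col += coincidence_columns(ct, t, aux_idx)[:, 0]
        col = col.reshape(ct.n_rates, ct.n_channels).sum(axis=0)
        e = [np.abs(tc.analyze(c, cfg).tensor.values).sum(axis=(0, 2))
             for c in truth.components]
        for k in range(2):
            own = e[k] > 3 * e[1 - k]
            # positive coincidence with the majority of each source's channels
            assert np.mean(col[: ana.tensor.n_channels][own] > 0) > 0.5

    def test_length_mismatch_rejected(self, cfg):
        mix, _ = tc.gen_alternating_tones(400, 1000, reps=2)
        ana = tc.analyze(mix, cfg)
        with pytest.raises(ValueError, match="frames"):
            tc.augment_with_aux(ana.tensor, np.ones(10), cfg)
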