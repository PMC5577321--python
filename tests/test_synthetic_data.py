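"""Phantom generator: config validation, fraction targeting, determinism,
round trips, and the directional structure the analysis relies on."""

import dataclasses
import math

import numpy as np
import pytest

import stromap as sm
from conftest import small_config


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"image_size_px": (128, 512)},
            {"pixel_size_um": 0.05},
            {"pixel_size_um": 11.0},
            {"n_sites": 0},
            {"collagen_target_fraction": 1.2},
            {"complexity": -0.1},
            {"encapsulation": 2.0},
            {"vessel_density_base": -0.5},
            {"pressure_noise_sd_mmHg": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)

    def test_yaml_roundtrip_and_unknown_keys(self, tmp_path):
        cfg = small_config(collagen_target_fraction=0.25)
        p = tmp_path / "cfg.yaml"
        sm.synthetic_data.save_config(cfg, p)
        assert sm.synthetic_data.load_config(p) == cfg
        p.write_text(p.read_text() + "\nbogus_key: 3\n")
        with pytest.raises(ValueError, match="bogus_key"):
            sm.synthetic_data.load_config(p)


class TestCollagenField:
    def test_mask_fraction_hits_target(self):
        cfg = small_config(collagen_target_fraction=0.30, seed=1)
        _, mask = sm.generate_collagen_field(cfg)
        # fraction inside the tumor matches the target within 2 points
        tumor = sm.synthetic_data._tumor_mask(cfg, np.random.default_rng(1))
        frac = mask.area_fraction(tumor)
        assert 0.28 <= frac <= 0.32

    def test_zero_target_gives_empty_mask(self):
        _, mask = sm.generate_collagen_field(small_config(collagen_target_fraction=0.0))
        assert not mask.values.any()

    def test_full_target_fills_tumor(self):
        cfg = small_config(collagen_target_fraction=1.0, seed=2)
        _, mask = sm.generate_collagen_field(cfg)
        assert mask.area_fraction() > 0.5  # everything inside the tumor

    def test_field_in_unit_interval(self):
        field, _ = sm.generate_collagen_field(small_config(seed=3))
        assert field.min() >= 0.0 and field.max() <= 1.0

    def test_complexity_raises_entropy_and_dimension(self):
        """Across 20 seeds, complexity 0.8 fields have higher mean entropy
        and fractal dimension than complexity 0.2 fields (texture metrics
        as the oracle)."""
        stats = {0.2: [], 0.8: []}
        for cx in stats:
            for seed in range(20):
                cfg = small_config(
                    image_size_px=(256, 256), complexity=cx, seed=seed,
                    collagen_target_fraction=0.3,
                )
                _, mask = sm.generate_collagen_field(cfg)
                prof = sm.texture_profile(mask, window_px=16, n_bins=32)
                stats[cx].append((prof.entropy_bits, prof.fractal_D))
        lo, hi = np.array(stats[0.2]), np.array(stats[0.8])
        assert hi[:, 0].mean() > lo[:, 0].mean()  # entropy
        assert hi[:, 1].mean() > lo[:, 1].mean()  # fractal dimension


class TestPhantom:
    def test_rasters_aligned_and_masks_nested(self, small_phantom):
        ph = small_phantom
        shape = ph.tumor_mask.shape
        for img in (ph.mt_image, ph.habp_image, ph.lectin_image,
                    ph.verteporfin_image):
            assert img.shape == shape
            assert img.pixel_size_um == ph.tumor_mask.pixel_size_um
        for m in (ph.truth_collagen, ph.truth_ha, ph.truth_vessels):
            assert m.is_subset_of(ph.tumor_mask)
        assert not (ph.truth_collagen.values & ph.truth_ha.values).any()

    def test_sites_inside_tumor_and_separated(self, small_phantom):
        ph = small_phantom
        min_sep_px = ph.config.min_site_separation_mm * 1000 / ph.config.pixel_size_um
        centers = [s.center_px for s in ph.sites]
        for x, y in centers:
            assert ph.tumor_mask.values[int(y), int(x)]
        for i, a in enumerate(centers):
            for b in centers[i + 1:]:
                assert math.dist(a, b) >= min_sep_px

    def test_noiseless_records_equal_model_predictions(self):
        cfg = small_config(pressure_noise_sd_mmHg=0.0, seed=5)
        ph = sm.generate_phantom(cfg)
        bundle = ph.truth_bundle()
        for site, rec in zip(ph.sites, ph.records):
            q = sm.quantify_site(bundle, site, cfg.roi_side_mm)
            if q.collagen_frac_pct > 0:
                expected = sm.predict_ttp(q.ha_frac_pct, q.collagen_frac_pct,
                                          cfg.model_params)
            else:  # collagen-free ROI: the high-ratio limit applies
                expected = cfg.model_params.ifp_mmHg
            assert rec.ttp_mmHg == pytest.approx(expected, abs=1e-9)
        assert ph.records[0].ifp_mmHg == pytest.approx(cfg.model_params.ifp_mmHg)
        assert all(r.ifp_mmHg is None for r in ph.records[1:])

    def test_noiseless_fit_recovers_generating_params(self):
        """With zero pressure noise the SS_swell fit inverts the generator
        exactly (R^2 = 1)."""
        cfg = small_config(pressure_noise_sd_mmHg=0.0, n_sites=3,
                           min_site_separation_mm=0.25, seed=8)
        ph = sm.generate_phantom(cfg)
        bundle = ph.truth_bundle()
        obs = []
        for site, rec in zip(ph.sites, ph.records):
            q = sm.quantify_site(bundle, site, cfg.roi_side_mm)
            obs.append(sm.TumorObservation(rec.ttp_mmHg, q.ha_frac_pct,
                                           q.collagen_frac_pct))
        params, r2, _ = sm.fit_ss_swell(obs, cfg.model_params.ifp_mmHg)
        assert params.ss_swell_mmHg == pytest.approx(
            cfg.model_params.ss_swell_mmHg, abs=0.05
        )
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_same_seed_reproduces_encoded_bytes(self, tmp_path):
        cfg = small_config(seed=21)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        p1 = sm.write_phantom(sm.generate_phantom(cfg), d1)
        p2 = sm.write_phantom(sm.generate_phantom(cfg), d2)
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key

    def test_impossible_site_placement_fails(self):
        with pytest.raises(ValueError, match="cannot place"):
            sm.generate_phantom(small_config(n_sites=10, min_site_separation_mm=2.0))

    def test_vessels_avoid_encapsulated_ha(self):
        """Over 20 seeds, vessel density inside HA pools is lower when the
        pools are collagen-encapsulated than when they are open: the ring
        raises local TTP, which suppresses patent vessels."""
        density = {0.0: [], 1.0: []}
        for enc in density:
            for seed in range(20):
                cfg = small_config(
                    image_size_px=(384, 384), encapsulation=enc, seed=seed,
                    ha_pool_radius_um=80.0, vessel_density_base=0.08, n_sites=1,
                )
                ph = sm.generate_phantom(cfg)
                ha, v = ph.truth_ha.values, ph.truth_vessels.values
                if ha.sum() == 0:
                    continue
                density[enc].append(v[ha].mean())
        assert min(len(d) for d in density.values()) >= 15
        assert np.mean(density[1.0]) < np.mean(density[0.0])


class TestRendering:
    def test_rendered_ha_pixels_satisfy_red_dominance(self, small_phantom):
        ph = small_phantom
        px = ph.habp_image.pixels.astype(int)
        ha = ph.truth_ha.values
        assert (px[ha, 0] > 2 * px[ha, 1]).all()
        assert (px[ha, 0] > 2 * px[ha, 2]).all()

    def test_background_rendered_white_and_never_ha(self, small_phantom):
        ph = small_phantom
        bg = ~ph.tumor_mask.values
        assert (ph.habp_image.pixels[bg] == 255).all()
        assert not sm.segment_ha_habp(ph.habp_image).values[bg].any()

    def test_all_collagen_tumor_recovers_100_percent(self):
        cfg = small_config()
        tumor = sm.synthetic_data._tumor_mask(cfg, np.random.default_rng(0))
        mt = sm.render_mt_image(tumor, tumor)
        seg = sm.segment_collagen_mt(mt)
        assert (seg.values == tumor.values).all()

    def test_empty_masks_recover_zero(self):
        cfg = small_config()
        tumor = sm.synthetic_data._tumor_mask(cfg, np.random.default_rng(0))
        empty = sm.BinaryMask(np.zeros(tumor.shape, bool), cfg.pixel_size_um)
        assert not sm.segment_collagen_mt(sm.render_mt_image(empty, tumor)).values.any()
        assert not sm.segment_ha_habp(sm.render_habp_image(empty, tumor)).values.any()

    def test_fluorescence_rendering_thresholds_cleanly(self, rng):
        mask = sm.BinaryMask(rng.random((128, 128)) > 0.9, 2.0)
        img = sm.render_fluorescence(mask, gain=100.0, rng=rng)
        seg = sm.segment_lectin(img, 30.0)
        assert np.array_equal(seg.values, mask.values)

    def test_shape_mismatch_rejected(self):
        a = sm.BinaryMask(np.zeros((64, 64), bool), 2.0)
        b = sm.BinaryMask(np.zeros((65, 64), bool), 2.0)
        with pytest.raises(ValueError):
            sm.render_mt_image(a, b)

    def test_verteporfin_decreases_with_local_ttp(self, small_phantom):
        """Mean verteporfin intensity ranks opposite to the modelled TTP of
        each ROI (uptake falls where pressure is high)."""
        ph = small_phantom
        bundle = ph.truth_bundle()
        qs = [sm.quantify_site(bundle, s, 0.5) for s in ph.sites]

        def model_ttp(q):
            if q.collagen_frac_pct == 0:
                return ph.config.model_params.ifp_mmHg
            return sm.predict_ttp(
                q.ha_frac_pct, q.collagen_frac_pct, ph.config.model_params
            )

        qs = sorted(qs, key=model_ttp)
        assert qs[0].verteporfin_mean >= qs[-1].verteporfin_mean
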