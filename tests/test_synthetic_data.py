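import numpy as np
import pytest
from scipy import stats

from lymphwalk import kinematics
from lymphwalk.synthetic_data import (DEFAULT_ANGLES, DEFAULT_SPEED,
                                      GeneratorSpec, HotspotRegion,
                                      default_hotspot_regions, gen_field,
                                      gen_hotspot_field)


class TestGenField:
    @pytest.mark.parametrize("model", ["brownian", "crw", "lognormal",
                                       "logmcrw", "powerlaw", "mixture"])
    def test_deterministic_given_seed(self, model):
        spec = GeneratorSpec(model=model, n_tracks=10, seed=42)
        a, _ = gen_field(spec)
        b, _ = gen_field(GeneratorSpec(model=model, n_tracks=10, seed=42))
        for ta, tb in zip(a.tracks, b.tracks):
            np.testing.assert_array_equal(ta.xyz, tb.xyz)

    def test_tracks_respect_spec(self):
        spec = GeneratorSpec(model="logmcrw", n_tracks=30, seed=1)
        field, truth = gen_field(spec)
        assert field.n_tracks == 30
        assert truth["model"] == "logmcrw"
        lo, hi = field.bbox
        for tr in field.tracks:
            assert tr.duration <= 600.0
            np.testing.assert_allclose(np.diff(tr.t), spec.frame_dt)
            assert np.all(tr.xyz >= lo - 1e-9) and np.all(tr.xyz <= hi + 1e-9)
            tr.validate()

    def test_speed_distribution_ks(self):
        field, _ = gen_field(GeneratorSpec(model="logmcrw", n_tracks=400,
                                           seed=5))
        sp = np.concatenate([kinematics.speeds(tr) for tr in field.tracks])
        assert len(sp) > 8000
        p = stats.kstest(np.log(sp), "norm",
                         args=(DEFAULT_SPEED["mu"], DEFAULT_SPEED["sigma"])).pvalue
        assert p > 0.01

    def test_angle_distribution_ks(self):
        field, _ = gen_field(GeneratorSpec(model="crw", n_tracks=400, seed=6,
                                           speed_params={"mu": 0.13,
                                                         "sigma": 0.02}))
        ang = np.concatenate([kinematics.turning_angle_values(tr)
                              for tr in field.tracks])
        p = stats.kstest(ang, stats.gamma(a=DEFAULT_ANGLES["shape"],
                                          scale=DEFAULT_ANGLES["scale"]).cdf).pvalue
        assert p > 0.01

    def test_speed_refit_recovers_parameters(self):
        field, _ = gen_field(GeneratorSpec(model="logmcrw", n_tracks=4000,
                                           duration_range=(400, 600), seed=3))
        from lymphwalk import distributions

        sp = np.concatenate([kinematics.speeds(tr) for tr in field.tracks])
        fit = distributions.fit_mle(sp[sp > 0], "lognormal")
        assert fit.params["mu"] == pytest.approx(DEFAULT_SPEED["mu"], rel=0.02)
        assert fit.params["sigma"] == pytest.approx(DEFAULT_SPEED["sigma"],
                                                    rel=0.02)

    def test_powerlaw_field_has_heavy_step_tail(self):
        from lymphwalk import distributions

        field, _ = gen_field(GeneratorSpec(model="powerlaw", n_tracks=400,
                                           duration_range=(400, 600), seed=4))
        steps = np.concatenate([kinematics.step_lengths(tr)
                                for tr in field.tracks])
        tail = distributions.fit_powerlaw_tail(steps[steps > 0])
        # finite tracks truncate the largest steps, biasing the exponent
        # upward; the tail must still be unambiguously heavy
        assert tail.mu < 3.5
        assert tail.tail_fraction > 0.1

    def test_mixture_labels(self):
        field, truth = gen_field(GeneratorSpec(model="mixture", n_tracks=20,
                                               seed=9))
        assert truth["labels"].count("slow") == 10
        assert field.n_tracks == 20

    @pytest.mark.parametrize("bad", [
        dict(model="teleport"),
        dict(n_tracks=0),
        dict(duration_range=(0.0, 700.0)),
        dict(frame_dt=-1.0),
    ])
    def test_invalid_spec(self, bad):
        with pytest.raises(ValueError):
            gen_field(GeneratorSpec(**bad, seed=0))


class TestHotspotField:
    def test_requires_regions(self):
        with pytest.raises(ValueError, match="regions"):
            gen_hotspot_field(GeneratorSpec(seed=0))

    def test_region_outside_box_rejected(self):
        reg = HotspotRegion(center=(395.0, 10.0, 25.0), radius=20.0)
        with pytest.raises(ValueError, match="outside"):
            gen_field(GeneratorSpec(hotspot_regions=[reg], seed=0))

    def test_region_mask_and_slowdown(self):
        regions = default_hotspot_regions(strong=True)
        spec = GeneratorSpec(model="logmcrw", n_tracks=120,
                             hotspot_regions=regions, seed=11)
        field, truth = gen_hotspot_field(spec)
        mask = truth["region_cubes"]
        assert mask
        lo = field.bbox[0]
        for cube in mask:
            center = lo + (np.array(cube) + 0.5) * 20.0
            assert min(np.linalg.norm(center - r.center) for r in regions) \
                <= regions[0].radius
        # walkers inside regions move slower than walkers outside
        inside, outside = [], []
        for tr in field.tracks:
            sp = kinematics.speeds(tr)
            pos = tr.xyz[:-1]
            d = np.min([np.linalg.norm(pos - r.center, axis=1)
                        for r in regions], axis=0)
            inside.extend(sp[d < regions[0].radius])
            outside.extend(sp[d > regions[0].radius + 30.0])
        assert np.median(inside) < np.median(outside)

    def test_zero_bias_matches_plain_field(self):
        regions = default_hotspot_regions(strong=False)
        spec = GeneratorSpec(model="logmcrw", n_tracks=15,
                             hotspot_regions=regions, seed=21)
        with_regions, _ = gen_hotspot_field(spec)
        plain, _ = gen_field(GeneratorSpec(model="logmcrw", n_tracks=15,
                                           seed=21))
        for ta, tb in zip(with_regions.tracks, plain.tracks):
            np.testing.assert_allclose(ta.xyz, tb.xyz)
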