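"""Image readout: white balance, region means, device calibration, dose maps."""

import numpy as np
import pytest

from pcidose.calibration import KineticCalibration
from pcidose.image_colorimetry import (AnnotatedImage, Region,
                                       device_dose_response, dose_image,
                                       read_annotations, read_image,
                                       region_color, region_lab, white_balance,
                                       write_dose_map)
from pcidose.synthetic import SyntheticSpec, gen_swatch_image


@pytest.fixture(scope="module")
def spec():
    return SyntheticSpec(seed=0)


def _flat_image(value=(0.5, 0.5, 0.5), size=32, white=0.9):
    img = np.empty((size, size, 3))
    img[:] = value
    img[:8, :, :] = white
    regions = [Region("white", "white", 0, 0, size, 8),
               Region("swatch", "exposed", 4, 12, size - 4, size - 4)]
    return AnnotatedImage(pixels=img, regions=regions, encoding="linear")


class TestWhiteBalance:
    def test_neutral_image_unchanged_up_to_exposure(self):
        img = _flat_image()
        out = white_balance(img, target=0.9)
        # white was already (0.9, 0.9, 0.9): identity
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-12)

    def test_inverts_channel_gains(self):
        img = _flat_image()
        gains = np.array([1.05, 1.0, 0.8])
        casted = AnnotatedImage(pixels=np.clip(img.pixels * gains, 0, 1),
                                regions=img.regions, encoding="linear")
        out = white_balance(casted, target=0.9)
        white = out.pixels[:8].reshape(-1, 3).mean(axis=0)
        np.testing.assert_allclose(white, 0.9, atol=1e-6)
        swatch = out.pixels[12:, 4:-4].reshape(-1, 3).mean(axis=0)
        np.testing.assert_allclose(swatch, 0.5, atol=1e-6)

    def test_idempotent(self):
        img = _flat_image(value=(0.3, 0.5, 0.7))
        once = white_balance(img)
        twice = white_balance(once)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-9)

    def test_zero_white_channel_rejected(self):
        img = _flat_image()
        broken = img.pixels.copy()
        broken[:8, :, 2] = 0.0
        bad = AnnotatedImage(pixels=broken, regions=img.regions, encoding="linear")
        with pytest.raises(ValueError, match="zero-mean"):
            white_balance(bad)

    def test_missing_white_region_rejected(self):
        img = AnnotatedImage(pixels=np.full((16, 16, 3), 0.5),
                             regions=[Region("s", "exposed", 0, 0, 16, 16)])
        with pytest.raises(KeyError):
            white_balance(img)


class TestRegionColor:
    def test_uniform_and_binary_regions(self):
        img = _flat_image(value=(0.25, 0.5, 0.75))
        c = region_color(img, img.find("exposed"))
        np.testing.assert_allclose(c.as_array(), [0.25, 0.5, 0.75], atol=1e-12)

        px = np.zeros((10, 10, 3))
        px[:, 5:, :] = 1.0
        half = AnnotatedImage(pixels=px, regions=[Region("r", "exposed", 0, 0, 10, 10)])
        np.testing.assert_allclose(
            region_color(half, half.find("exposed")).as_array(), 0.5, atol=1e-12)

    def test_matches_brute_force_pixel_loop(self):
        rng = np.random.default_rng(3)
        px = rng.uniform(0, 1, (20, 24, 3))
        reg = Region("r", "exposed", 3, 5, 17, 13)
        img = AnnotatedImage(pixels=px, regions=[reg])
        got = region_color(img, reg).as_array()
        acc = np.zeros(3)
        cnt = 0
        for y in range(5, 13):
            for x in range(3, 17):
                acc += px[y, x]
                cnt += 1
        np.testing.assert_allclose(got, acc / cnt, atol=1e-12)

    def test_subdivision_invariance(self):
        rng = np.random.default_rng(4)
        px = rng.uniform(0, 1, (16, 16, 3))
        whole = Region("w", "exposed", 0, 0, 16, 16)
        top = Region("t", "exposed", 0, 0, 16, 6)
        bottom = Region("b", "exposed", 0, 6, 16, 16)
        img = AnnotatedImage(pixels=px, regions=[whole, top, bottom])
        mw = region_color(img, whole).as_array()
        mt = region_color(img, top).as_array()
        mb = region_color(img, bottom).as_array()
        weighted = (mt * top.area + mb * bottom.area) / whole.area
        np.testing.assert_allclose(mw, weighted, atol=1e-12)

    def test_region_bounds_checked(self):
        with pytest.raises(ValueError, match="bounds"):
            AnnotatedImage(pixels=np.zeros((8, 8, 3)),
                           regions=[Region("r", "exposed", 0, 0, 9, 8)])


class TestDeviceDoseResponse:
    def test_recovers_generating_parameters(self, spec):
        imgs = [gen_swatch_image(float(d), spec)
                for d in np.linspace(0, 250, 8)]
        data = device_dose_response(imgs, s_delta_e=0.273)
        m = KineticCalibration("first").fit(data)
        assert abs(m.a_ - spec.a_true) / spec.a_true < 0.05
        assert abs(m.b_ - spec.b_true) / spec.b_true < 0.05

    def test_two_devices_agree_after_white_balance(self, spec):
        doses = np.linspace(0, 250, 8)
        d1 = device_dose_response(
            [gen_swatch_image(float(d), spec, channel_gains=(1.2, 1.0, 0.8))
             for d in doses])
        d2 = device_dose_response(
            [gen_swatch_image(float(d), spec, channel_gains=(0.9, 1.0, 1.1))
             for d in doses])
        m1 = KineticCalibration("first").fit(d1)
        m2 = KineticCalibration("first").fit(d2)
        assert m1.b_ == pytest.approx(m2.b_, rel=0.05)

    def test_zero_dose_delta_e_near_zero(self, spec):
        img = gen_swatch_image(0.0, spec)
        data = device_dose_response(
            [img] + [gen_swatch_image(float(d), spec) for d in (50, 100, 200)])
        assert data.delta_e[0] < 0.5

    def test_missing_reference_rejected(self, spec):
        img = gen_swatch_image(100.0, spec)
        img.regions = [r for r in img.regions if r.role != "unexposed"]
        with pytest.raises(ValueError, match="unexposed"):
            device_dose_response([img] * 4)


@pytest.fixture(scope="module")
def model(spec):
    imgs = [gen_swatch_image(float(d), spec) for d in np.linspace(0, 250, 8)]
    return KineticCalibration("first").fit(device_dose_response(imgs))


class TestDoseImage:

    def test_uniform_swatch_matches_scalar_estimate(self, spec, model):
        img = gen_swatch_image(80.0, spec)
        bal = white_balance(img)
        ref = region_lab(bal, bal.find("unexposed"))
        doses, sat = dose_image(bal, model, ref, balance=False)
        reg = bal.find("exposed")
        med = float(np.nanmedian(doses[reg.slices()]))
        assert med == pytest.approx(80.0, rel=0.10)
        assert not sat[reg.slices()].any()

    def test_masked_swatch_is_bimodal(self, spec, model):
        img = gen_swatch_image(60.0, spec, mask_dose=150.0)
        bal = white_balance(img)
        ref = region_lab(bal, bal.find("unexposed"))
        doses, _ = dose_image(bal, model, ref, balance=False)
        lo = float(np.nanmedian(doses[bal.find("exposed", "exposed").slices()]))
        hi = float(np.nanmedian(doses[bal.find("exposed", "masked").slices()]))
        assert lo == pytest.approx(60.0, rel=0.10)
        assert hi == pytest.approx(150.0, rel=0.10)

    def test_unexposed_maps_to_zero_and_saturated_is_flagged(self, spec, model):
        img = gen_swatch_image(0.0, spec)
        bal = white_balance(img)
        ref = region_lab(bal, bal.find("unexposed"))
        doses, sat = dose_image(bal, model, ref, balance=False)
        reg = bal.find("unexposed")
        assert float(np.nanmedian(doses[reg.slices()])) == pytest.approx(0.0, abs=2.0)
        # the saturated reference patch must be flagged, not clipped
        sat_reg = bal.find("saturated")
        assert sat[sat_reg.slices()].mean() > 0.9
        assert np.isnan(doses[sat_reg.slices()]).mean() > 0.9


class TestIO:
    def test_image_round_trip_uint16(self, tmp_path, spec):
        import tifffile

        img = gen_swatch_image(100.0, spec)
        p = tmp_path / "swatch.tif"
        tifffile.imwrite(p, (img.pixels * 65535).astype(np.uint16))
        back = read_image(p, encoding="linear")
        assert back.bit_depth == 16
        np.testing.assert_allclose(back.pixels, img.pixels, atol=1 / 65535)

    def test_annotation_csv(self, tmp_path):
        p = tmp_path / "ann.csv"
        p.write_text("image,region_name,role,x0,y0,x1,y1\n"
                     "a.tif,white,white,0,0,10,5\n"
                     "a.tif,pci,exposed,2,6,8,12\n")
        ann = read_annotations(p)
        assert len(ann["a.tif"]) == 2
        assert ann["a.tif"][0].role == "white"

    def test_dose_map_output(self, tmp_path):
        import tifffile

        doses = np.array([[1.0, np.nan], [3.0, 4.0]])
        tif = tmp_path / "map.tif"
        csv = tmp_path / "map.csv"
        write_dose_map(doses, tif, csv_path=csv)
        back = tifffile.imread(tif)
        assert back.dtype == np.float32
        assert np.isnan(back[0, 1])
        text = csv.read_text()
        assert "n_saturated" in text
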