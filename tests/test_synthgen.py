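"""Generator invariants: label hierarchy, determinism, rendering geometry,
and the morphology-signal calibration."""

import numpy as np
import pytest

from sonomtl.errors import ConfigurationError, GenerationError
from sonomtl.synthgen import (
    LesionParams,
    SyntheticConfig,
    generate_dataset,
    render_image,
    sample_labels,
    sample_lesion_params,
    sample_patient,
    write_dataset,
)


def test_hierarchy_holds_for_every_record():
    records = generate_dataset(SyntheticConfig(n_patients=50, seed=11))
    for r in records:
        assert r.alnm <= r.bm
        assert (r.node_count >= 1) == (r.alnm == 1)
        assert r.alnm_defined == (r.bm == 1)


@pytest.mark.parametrize(
    "p_mal, p_alnm, expect",
    [(0.0, 0.5, "all_negative"), (1.0, 1.0, "all_positive")],
)
def test_degenerate_prevalences_force_labels(p_mal, p_alnm, expect):
    cfg = SyntheticConfig(n_patients=10, p_malignant=p_mal,
                          p_alnm_given_malignant=p_alnm, seed=2)
    records = generate_dataset(cfg)
    if expect == "all_negative":
        assert all(r.bm == 0 and r.alnm == 0 and r.node_count == 0 for r in records)
    else:
        assert all(r.bm == 1 and r.alnm == 1 and r.node_count >= 1 for r in records)


def test_invalid_probability_rejected():
    with pytest.raises(ConfigurationError):
        SyntheticConfig(p_malignant=1.5).validate()
    with pytest.raises(ConfigurationError):
        SyntheticConfig(burden_dist={1: 0.5, 2: 0.2}).validate()


def test_seeded_generation_is_byte_identical():
    cfg = SyntheticConfig(n_patients=6, seed=7)
    a = generate_dataset(cfg)
    b = generate_dataset(cfg)
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.image_id == rb.image_id
        assert ra.box == rb.box
        assert (ra.bm, ra.alnm, ra.node_count) == (rb.bm, rb.alnm, rb.node_count)
        np.testing.assert_array_equal(ra.pixels, rb.pixels)


def test_patient_records_share_labels_and_id():
    cfg = SyntheticConfig(seed=3)
    recs = sample_patient(cfg, np.random.default_rng(3), patient_id="PX")
    assert 1 <= len(recs) <= 4
    assert len({(r.patient_id, r.bm, r.alnm, r.node_count) for r in recs}) == 1


def _plain_ellipse(core=85.0, cx=64.0, cy=60.0, a=18.0, b=12.0, theta=0.4):
    return LesionParams(center=(cx, cy), semi_axes=(a, b), orientation=theta,
                        spiculation_amp=0.0, margin_blur=0.0, core_intensity=core,
                        halo_intensity=0.0)


def test_noise_free_render_is_binary_with_bruteforce_box():
    """With no spiculation/blur/speckle the image is a two-valued ellipse and
    the stored box matches an independent per-pixel scan of the ellipse
    equation."""
    params = _plain_ellipse()
    cfg = SyntheticConfig(speckle_scale=0.0)
    img, box = render_image(params, cfg, np.random.default_rng(0))
    assert set(np.unique(img)) <= {85, 140}

    cx, cy = params.center
    a, b = params.semi_axes
    c, s = np.cos(params.orientation), np.sin(params.orientation)
    xs, ys = [], []
    for y in range(cfg.image_size):
        for x in range(cfg.image_size):
            u = (c * (x - cx) + s * (y - cy)) / a
            v = (-s * (x - cx) + c * (y - cy)) / b
            if u * u + v * v <= 1.0:
                xs.append(x)
                ys.append(y)
    assert box == (min(xs), min(ys), max(xs) + 1, max(ys) + 1)
    inside = img == 85
    assert inside.sum() == len(xs)


def test_no_contrast_no_speckle_gives_constant_image():
    params = _plain_ellipse(core=140.0)
    img, _ = render_image(params, SyntheticConfig(speckle_scale=0.0),
                          np.random.default_rng(0))
    assert (img == 140).all()


def test_render_is_seed_deterministic():
    params = _plain_ellipse()
    cfg = SyntheticConfig()
    a, _ = render_image(params, cfg, np.random.default_rng(42))
    b, _ = render_image(params, cfg, np.random.default_rng(42))
    np.testing.assert_array_equal(a, b)


def test_out_of_bounds_lesion_raises():
    params = _plain_ellipse(cx=3.0, cy=3.0)
    with pytest.raises(GenerationError):
        render_image(params, SyntheticConfig(speckle_scale=0.0), np.random.default_rng(0))


def test_zero_effect_size_equalizes_classes_across_seeds():
    """With effect_size=0 the spiculation distribution must be identical for
    benign and malignant lesions: a two-sample KS test at alpha=0.01 should
    not reject in at least 19 of 20 seeded draws."""
    from scipy.stats import ks_2samp

    non_reject = 0
    for seed in range(20):
        g = np.random.default_rng(seed)
        cfg = SyntheticConfig(effect_size=0.0)
        spic = {0: [], 1: []}
        for _ in range(500):
            bm, alnm, count = sample_labels(cfg, g)
            p = sample_lesion_params(cfg, bm, alnm, count, g)
            spic[bm].append(p.spiculation_amp)
        if ks_2samp(spic[0], spic[1]).pvalue >= 0.01:
            non_reject += 1
    assert non_reject >= 19


def test_large_effect_size_separates_spiculation():
    """At 2-sigma separation a threshold on spiculation alone classifies
    malignancy with AUC > 0.9 (computed directly on sampled parameters)."""
    from sklearn.metrics import roc_auc_score

    g = np.random.default_rng(0)
    cfg = SyntheticConfig(effect_size=2.0)
    ys, amps = [], []
    for _ in range(2000):
        bm, alnm, count = sample_labels(cfg, g)
        ys.append(bm)
        amps.append(sample_lesion_params(cfg, bm, alnm, count, g).spiculation_amp)
    assert roc_auc_score(ys, amps) > 0.9


def test_write_dataset_layout(tmp_path):
    cfg = SyntheticConfig(n_patients=3, images_per_patient={2: 1.0},
                          images_per_patient_benign={2: 1.0}, seed=9)
    records = generate_dataset(cfg)
    assert len(records) == 6
    manifest = write_dataset(records, tmp_path)
    assert manifest.exists()
    assert len(list((tmp_path / "images").glob("*.png"))) == 6
    assert len(list((tmp_path / "annotations").glob("*.xml"))) == 6
    assert sum(1 for _ in open(manifest)) == 7  # header + 6 rows
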