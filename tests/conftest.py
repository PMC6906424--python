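import numpy as np
import pytest

from proj2proj import ConeBeamGeometry, Volume, make_phantom, render_pair


@pytest.fixture(scope="session")
def small_geometry():
    """Odd detector so a central pixel ray passes exactly through the isocenter."""
    return ConeBeamGeometry(
        source_to_isocenter_mm=600.0,
        source_to_detector_mm=1200.0,
        detector_shape=(65, 65),
        detector_spacing_mm=(4.0, 4.0),
    )


@pytest.fixture(scope="session")
def ball_volume():
    """Uniform ball: radius 20 mm, attenuation 0.01 / mm, 64^3 grid at 1 mm."""
    n = 64
    x = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    ball = ((X**2 + Y**2 + Z**2) <= 20.0**2).astype(float) * 0.01
    return Volume.centered(ball, (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def phantom_volumes():
    """Seeded 64^3 phantom rendered into (mr_volume, xray_volume)."""
    phantom = make_phantom((64, 64, 64), seed=7, n_inner_structures=5)
    return render_pair(phantom)


def build_memory_dataset(n_subjects=2, n_train=6, n_test=4, seed=21,
                         detector=(32, 32), pitch=8.0, phantom_n=32, phantom_mm=2.0):
    """Small in-memory paired dataset (no disk I/O) for training tests."""
    from proj2proj import make_trajectory, project_pair
    from proj2proj.train import PairedDataset

    geo = ConeBeamGeometry(detector_shape=detector, detector_spacing_mm=(pitch, pitch))
    train_views = make_trajectory(n_train, "training_sphere")
    test_views = make_trajectory(n_test, "test_transversal")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        phantom = make_phantom((phantom_n,) * 3, spacing_mm=(phantom_mm,) * 3,
                               seed=int(rng.integers(0, 2**31 - 1)))
        mr_vol, xr_vol = render_pair(phantom)
        entry = {
            "train": [project_pair(mr_vol, xr_vol, geo, v, 1.0) for v in train_views],
            "test": [project_pair(mr_vol, xr_vol, geo, v, 1.0) for v in test_views],
        }
        subjects.append(entry)
    return PairedDataset(subjects)


@pytest.fixture(scope="session")
def tiny_dataset():
    return build_memory_dataset()


def trilinear_sample(values, spacing, origin, points):
    """Hand-rolled trilinear interpolation (independent of the projector's
    interpolation path); points outside the grid sample as zero."""
    idx = (np.asarray(points) - origin) / spacing
    out = np.zeros(len(idx))
    shape = np.array(values.shape)
    i0 = np.floor(idx).astype(int)
    frac = idx - i0
    for corner in range(8):
        offs = np.array([(corner >> k) & 1 for k in range(3)])
        ci = i0 + offs
        w = np.prod(np.where(offs == 1, frac, 1.0 - frac), axis=1)
        valid = np.all((ci >= 0) & (ci < shape), axis=1)
        vals = np.zeros(len(idx))
        vals[valid] = values[ci[valid, 0], ci[valid, 1], ci[valid, 2]]
        out += w * vals
    return out


def quadrature_line_integral(volume, ray, t_max=2000.0, step=0.03125):
    """Dense midpoint quadrature of the trilinear interpolant along a ray."""
    t = np.arange(0.0, t_max, step) + step / 2
    pts = ray.x0[None, :] + t[:, None] * ray.theta[None, :]
    vals = trilinear_sample(volume.values, volume.spacing_mm, volume.origin_mm, pts)
    return float(vals.sum() * step)
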