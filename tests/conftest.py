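import numpy as np
import pytest

from echolvef import LVShapeSpec, RhythmSpec, make_axis_curves, render_masks, simulate


@pytest.fixture(scope="session")
def sinus_echo():
    """Three regular cycles, EF 55%, rasterised with speckle."""
    rhythm = RhythmSpec(n_cycles=3, mean_period=40, seed=1)
    shape = LVShapeSpec(per_cycle_ef=(55.0, 55.0, 55.0))
    return simulate(rhythm, shape, snr=5.0)


@pytest.fixture(scope="session")
def af_curve_factory():
    """Seeded factory for irregular-rhythm analytic area/length curves."""

    def make(seed, n_cycles=3, mean_period=45, period_cv=0.3, efs=None):
        efs = efs or tuple([50.0] * n_cycles)
        rhythm = RhythmSpec(
            n_cycles=n_cycles, mean_period=mean_period, period_cv=period_cv, seed=seed
        )
        return make_axis_curves(rhythm, LVShapeSpec(per_cycle_ef=efs))

    return make


@pytest.fixture(scope="session")
def overfit_fixture():
    """Ten speckled frames and their truth masks for overfit training."""
    rhythm = RhythmSpec(n_cycles=1, mean_period=20, seed=2)
    echo = simulate(rhythm, LVShapeSpec(per_cycle_ef=(55.0,)), snr=5.0, seed=2)
    return echo.video.frames[:10], echo.masks[:10]


@pytest.fixture(scope="session")
def length_rows():
    """500 (features, length) rows from rasterised ellipses, sigma=1 px noise."""
    from echolvef.geometry import extract_features

    rng = np.random.default_rng(0)
    rows = []
    for _ in range(500):
        L = rng.uniform(50, 90)
        D = rng.uniform(0.4, 0.6) * L
        ang = rng.uniform(0, np.pi)
        spec = LVShapeSpec(
            long_axis_ed=L, short_axis_ed=D, per_cycle_ef=(55.0,), orientation=ang
        )
        mask, _ = render_masks(np.array([L]), np.array([D]), spec)
        feats = extract_features(mask[0])
        rows.append((feats, feats.height + rng.normal(0.0, 1.0)))
    return rows
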