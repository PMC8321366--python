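import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_srgb_to_lab(rgb):
    """Independent hand-coded sRGB (D65/2°) -> CIELAB converter.

    Written from the standard definition (linearization, primaries matrix,
    CIE f-function) without reference to the package's conversion path.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    lin = np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    M = np.array(
        [
            [0.4124564, 0.3575761, 0.1804375],
            [0.2126729, 0.7151522, 0.0721750],
            [0.0193339, 0.1191920, 0.9503041],
        ]
    )
    xyz = lin @ M.T
    white = np.array([0.95047, 1.0, 1.08883])
    t = xyz / white
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def ellipse_points(center, semi_major, semi_minor, angle_deg, t):
    """Parametric ellipse sampler used by the fitting tests."""
    ang = np.radians(angle_deg)
    x = center[0] + semi_major * np.cos(t) * np.cos(ang) - semi_minor * np.sin(t) * np.sin(ang)
    y = center[1] + semi_major * np.cos(t) * np.sin(ang) + semi_minor * np.sin(t) * np.cos(ang)
    return np.column_stack([x, y])
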