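import numpy as np
import pytest

from lgequant.geometry import ContourSet, ImageStack, MyocardiumMask
from lgequant.phantom import PhantomSpec


def circle(cx, cy, r, n=360):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack((cx + r * np.cos(t), cy + r * np.sin(t)))


@pytest.fixture
def uniform_annulus_spec():
    """Noiseless uniform annulus, 90-degree transmural infarct, no grey."""
    return PhantomSpec(
        grid=(128, 128, 10),
        pixel_spacing=(1.0, 1.0),
        endo_radius_by_slice=[25.0] * 10,
        epi_radius_by_slice=[35.0] * 10,
        infarct_angular_extent=90.0,
        transmural_fraction=1.0,
        grey_zone_width=0.0,
        noise_sd=0.0,
        noise_model="gaussian",
    )


def analytic_stack(
    n=96, n_slices=4, r_en=20.0, r_ep=30.0, remote=100.0, values=None
):
    """Annulus stack with intensities painted from angular/radial rules.

    ``values(rr, theta_deg)`` returns a 2-D intensity override applied
    inside the myocardium; remote myocardium is ``remote`` elsewhere.
    Returns (stack, myocardium mask, rr, theta).
    """
    x = (np.arange(n) + 0.5) - n / 2
    xx, yy = np.meshgrid(x, x)
    rr = np.hypot(xx, yy)
    theta = np.degrees(np.arctan2(yy, xx)) % 360.0
    myo2d = (rr >= r_en) & (rr <= r_ep)
    si2d = np.zeros((n, n))
    si2d[myo2d] = remote
    if values is not None:
        override = values(rr, theta)
        sel = myo2d & ~np.isnan(override)
        si2d[sel] = override[sel]
    si = np.repeat(si2d[None], n_slices, axis=0)
    myo = np.repeat(myo2d[None], n_slices, axis=0)
    stack = ImageStack(
        intensities=si, pixel_spacing=(1.0, 1.0), slice_thickness=8.0
    )
    return stack, MyocardiumMask(mask=myo), rr, theta


def sector_values(level, extent_deg, center_deg=90.0, r_max=None):
    """values() helper: constant ``level`` within an angular sector."""

    def f(rr, theta):
        d = np.abs((theta - center_deg + 180.0) % 360.0 - 180.0)
        out = np.full_like(rr, np.nan)
        sel = d <= extent_deg / 2.0
        if r_max is not None:
            sel &= rr <= r_max
        out[sel] = level
        return out

    return f
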