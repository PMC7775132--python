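"""Synthetic CT-like nodule phantoms with exact ground truth.

Every stage of the pipeline is testable without clinical data through
these phantoms.  A smooth phantom is a bright spherical blob — small
area, high luminance, smooth boundary, the morphology of a benign
nodule.  A spiculated phantom adds radial, unbranched strip "spikes"
extending from the blob boundary on the central slice, the defining
morphology of the spiculation sign.  The ground-truth mask is the
half-intensity isocontour of the noise-free phantom, computed in closed
form, and additive Gaussian noise is applied only after the truth is
extracted — so the truth is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .imaging_io import Image2D, ImageStack, Mask2D

__all__ = ["PhantomSpec", "PhantomCase", "make_nodule", "make_dataset", "make_u_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of one synthetic nodule.

    All lengths are in pixels; intensities on the [0, 1] gray scale.
    ``slice_spacing`` is the out-of-plane distance between adjacent
    slices, so the blob's in-plane radius on slice k is
    sqrt(radius² − (Δk · slice_spacing)²).
    """

    canvas: tuple[int, int, int] = (64, 64, 5)  # (height, width, n_slices)
    center: tuple[float, float, int] = (32.0, 32.0, 2)  # (row, col, slice)
    radius: float = 10.0
    n_spikes: int = 0
    spike_length: float = 8.0
    spike_width: float = 5.0
    nodule_intensity: float = 0.9
    background_intensity: float = 0.15
    noise_sigma: float = 0.02
    slice_spacing: float = 3.0
    edge_softness: float = 0.8  # logistic transition width of the blob rim
    seed: int = 0

    def __post_init__(self) -> None:
        h, w, n = self.canvas
        if h < 1 or w < 1 or n < 1:
            raise ValueError("canvas dimensions must be >= 1")
        if not (0 <= self.center[2] < n):
            raise ValueError("center slice outside canvas")
        if self.radius <= 0 or self.n_spikes < 0:
            raise ValueError("radius must be > 0 and n_spikes >= 0")
        if self.spike_length <= 0 or self.spike_width <= 0:
            raise ValueError("spike dimensions must be > 0")
        if not (0 <= self.background_intensity < self.nodule_intensity <= 1):
            raise ValueError("need 0 <= background < nodule intensity <= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        reach = self.radius + (self.spike_length if self.n_spikes else 0.0)
        r, c = self.center[:2]
        if not (reach <= r <= h - 1 - reach and reach <= c <= w - 1 - reach):
            raise ValueError("nodule (with spikes) does not fit inside the canvas")


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    spec: PhantomSpec
    stack: ImageStack
    truth: tuple[Mask2D, ...]
    label: int  # 1 = spiculated
    split: str  # "train" | "test"


def _spike_angles(n_spikes: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly jittered but well-separated radial directions, keeping the
    spikes unbranched and non-overlapping by construction."""
    base = 2.0 * np.pi * np.arange(n_spikes) / max(n_spikes, 1)
    jitter = rng.uniform(-0.3, 0.3, size=n_spikes) * 2.0 * np.pi / max(n_spikes, 1)
    return base + jitter + rng.uniform(0.0, 2.0 * np.pi)


def _profile_slice(spec: PhantomSpec, k: int, angles: np.ndarray) -> np.ndarray:
    """Noise-free normalized contrast profile of slice k in [0, 1].

    The nodule is modeled as a geometric shape — a disk plus, on the
    central slice, radial strip-shaped spicules tapering to a blunt end —
    rendered as a logistic function of the signed distance to the shape
    boundary (the partial-volume blur of a dense tissue region).  The
    ground truth is exactly {profile >= 0.5} = {signed distance >= 0},
    so the half-intensity isocontour, the geometric boundary and the
    intensity-gradient ridge all coincide.
    """
    h, w, _n = spec.canvas
    r0, c0, k0 = spec.center
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    dz = (k - k0) * spec.slice_spacing
    rk2 = spec.radius**2 - dz**2
    if rk2 <= 0:
        return np.zeros((h, w))
    rk = np.sqrt(rk2)
    sd = rk - np.hypot(rr - r0, cc - c0)  # signed distance to the disk
    if k == k0 and angles.size:
        import shapely
        from shapely.geometry import Polygon

        pts = shapely.points(cc.ravel(), rr.ravel())
        half = spec.spike_width / 2.0
        for theta in angles:
            er, ec = np.sin(theta), np.cos(theta)
            # wedge: base of width spike_width on the rim chord, apex at
            # radius + spike_length; rooted slightly inside the rim so
            # the union with the disk has no gap
            root = spec.radius - 1.0
            tip = spec.radius + spec.spike_length
            tip_half = min(1.0, half)  # blunt 2 px end: a strip, not a needle
            base_l = (c0 + root * ec - half * er, r0 + root * er + half * ec)
            base_r = (c0 + root * ec + half * er, r0 + root * er - half * ec)
            tip_l = (c0 + tip * ec - tip_half * er, r0 + tip * er + tip_half * ec)
            tip_r = (c0 + tip * ec + tip_half * er, r0 + tip * er - tip_half * ec)
            wedge = Polygon([base_l, base_r, tip_r, tip_l])
            inside = shapely.covers(wedge, pts)
            d_edge = shapely.distance(pts, wedge.exterior)
            sd_wedge = np.where(inside, d_edge, -d_edge).reshape(h, w)
            sd = np.maximum(sd, sd_wedge)
    return 1.0 / (1.0 + np.exp(-sd / spec.edge_softness))


def make_nodule(spec: PhantomSpec) -> tuple[ImageStack, list[Mask2D], int]:
    """Render one phantom: (image stack, per-slice truth masks, label).

    The image is background + contrast × profile with additive Gaussian
    noise; truth masks are the half-contrast isocontour of the
    noise-free profile; label is 1 iff the phantom carries spikes.
    """
    rng = np.random.default_rng(spec.seed)
    angles = _spike_angles(spec.n_spikes, rng) if spec.n_spikes else np.array([])
    h, w, n = spec.canvas
    contrast = spec.nodule_intensity - spec.background_intensity
    slices, truths = [], []
    for k in range(n):
        profile = _profile_slice(spec, k, angles)
        truths.append(Mask2D((profile >= 0.5).astype(np.uint8)))
        img = spec.background_intensity + contrast * profile
        if spec.noise_sigma > 0:
            img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
        slices.append(Image2D(np.clip(img, 0.0, 1.0)))
    return ImageStack(tuple(slices)), truths, int(spec.n_spikes > 0)


def make_dataset(
    n_per_class: int,
    base_spec: PhantomSpec | None = None,
    radius_jitter: float = 2.0,
    center_jitter: float = 2.0,
    intensity_jitter: float = 0.05,
    spike_range: tuple[int, int] = (8, 10),
    seed: int = 0,
) -> list[PhantomCase]:
    """Balanced smooth/spiculated phantom set with an exact 1:1
    train/test split inside each class.

    Radii, centers, intensities and spike counts are jittered per case;
    everything is deterministic in ``seed``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    rng = np.random.default_rng(seed)
    cases: list[PhantomCase] = []
    for label, tag in ((0, "smooth"), (1, "spic")):
        for i in range(n_per_class):
            case_seed = int(rng.integers(0, 2**31 - 1))
            r = base.radius + rng.uniform(-radius_jitter, radius_jitter)
            dr, dc = rng.uniform(-center_jitter, center_jitter, size=2)
            nod = np.clip(
                base.nodule_intensity + rng.uniform(-intensity_jitter, intensity_jitter),
                0.0, 1.0,
            )
            n_spikes = int(rng.integers(spike_range[0], spike_range[1] + 1)) if label else 0
            spec = replace(
                base,
                radius=float(r),
                center=(base.center[0] + dr, base.center[1] + dc, base.center[2]),
                nodule_intensity=float(nod),
                n_spikes=n_spikes,
                seed=case_seed,
            )
            stack, truth, _ = make_nodule(spec)
            split = "train" if i < (n_per_class + 1) // 2 else "test"
            cases.append(PhantomCase(
                case_id=f"{tag}_{i:03d}", spec=spec, stack=stack,
                truth=tuple(truth), label=label, split=split,
            ))
    return cases


def make_u_phantom(
    height: int = 64,
    width: int = 64,
    arm_width: int = 10,
    mouth_width: int = 8,
    depth: int = 28,
    intensity: float = 0.9,
    background: float = 0.15,
    softness: float = 0.8,
) -> tuple[Image2D, Mask2D]:
    """A U-shaped bright region with a deep concave mouth.

    The classic hard case for contour capture: an isotropically smoothed
    external force field cancels at the mouth of the concavity and the
    snake bridges it instead of descending.  Returns the image (smoothed
    rim, no noise) and the exact rectangular-geometry truth mask.
    """
    outer_w = mouth_width + 2 * arm_width
    r0 = (height - depth - arm_width) // 2
    c0 = (width - outer_w) // 2
    mask = np.zeros((height, width), dtype=bool)
    mask[r0:r0 + depth + arm_width, c0:c0 + outer_w] = True
    mask[r0:r0 + depth, c0 + arm_width:c0 + arm_width + mouth_width] = False

    from scipy.ndimage import distance_transform_edt

    inside = distance_transform_edt(mask)
    outside = distance_transform_edt(~mask)
    signed = np.where(mask, inside - 0.5, -(outside - 0.5))
    profile = 1.0 / (1.0 + np.exp(-signed / softness))
    img = background + (intensity - background) * profile
    return Image2D(img), Mask2D(mask.astype(np.uint8))
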