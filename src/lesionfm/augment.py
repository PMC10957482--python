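"""Stochastic 3D view generation for contrastive pretraining and fine-tuning.

The transform set adapts the 2D SimCLR recipe to CT patches: colour jitter
is replaced by a random monotone histogram intensity shift, and all spatial
transforms operate on [0, 1]-normalized cubes, mapping them back onto
[0, 1]-valued cubes of identical shape.  Exposed regions (translations,
rotations) are filled with 0, the normalized value of air, consistent with
patch border padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .types import Patch

KNOWN_TRANSFORMS = ("flip", "rot90", "rotate", "translate", "crop_resize", "blur",
                    "noise", "smooth_noise", "hist_shift")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which transforms run, with what probabilities and strengths."""

    transforms: Tuple[str, ...] = ()
    flip_prob: float = 0.5
    rotate_prob: float = 0.5
    free_rotate_max_deg: float = 20.0
    translate_voxels: int = 10
    crop_scale_range: Tuple[float, float] = (0.8, 1.0)
    blur_sigma_range: Tuple[float, float] = (0.0, 1.0)
    blur_prob: float = 0.5
    noise_sd: float = 0.05
    smooth_noise_sd: float = 0.02    # spatially correlated noise, matches the
    smooth_noise_sigma: float = 2.0  # scale of parenchymal background texture
    hist_points: int = 5
    hist_strength: float = 0.3

    def __post_init__(self) -> None:
        for t in self.transforms:
            if t not in KNOWN_TRANSFORMS:
                raise ValueError(f"unknown transform {t!r}; known: {KNOWN_TRANSFORMS}")
        if not 0 <= self.flip_prob <= 1 or not 0 <= self.rotate_prob <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.translate_voxels < 0:
            raise ValueError("translate bound must be >= 0")


def make_pretrain_policy(**overrides) -> AugmentationPolicy:
    """Default pretraining views: flips, free rotations, scaled crop-resize,
    Gaussian noise and the histogram intensity shift."""
    return replace(
        AugmentationPolicy(transforms=("flip", "rotate", "crop_resize", "noise",
                                       "smooth_noise", "hist_shift")),
        **overrides,
    )


def make_finetune_policy(**overrides) -> AugmentationPolicy:
    """Fine-tuning views: random flips, random 90-degree rotations and random
    translations of up to 10 voxels on every axis."""
    return replace(AugmentationPolicy(transforms=("flip", "rot90", "translate")), **overrides)


def identity_policy() -> AugmentationPolicy:
    return AugmentationPolicy(transforms=())


def _translate(values: np.ndarray, shifts: np.ndarray) -> np.ndarray:
    out = np.zeros_like(values)
    src = [slice(max(0, -s), values.shape[a] - max(0, s)) for a, s in enumerate(shifts)]
    dst = [slice(max(0, s), values.shape[a] - max(0, -s)) for a, s in enumerate(shifts)]
    out[tuple(dst)] = values[tuple(src)]
    return out


def _crop_resize(values: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    L = values.shape[0]
    cs = max(4, int(round(scale * L)))
    if cs >= L:
        return values
    lo = rng.integers(0, L - cs + 1, size=3)
    crop = values[lo[0]:lo[0] + cs, lo[1]:lo[1] + cs, lo[2]:lo[2] + cs]
    out = ndimage.zoom(crop, L / cs, order=1)
    for a in range(3):  # zoom can be off by one voxel; pad/crop to L exactly
        if out.shape[a] > L:
            out = out.take(range(L), axis=a)
        elif out.shape[a] < L:
            pad = [(0, 0)] * 3
            pad[a] = (0, L - out.shape[a])
            out = np.pad(out, pad, mode="edge")
    return out


def histogram_shift(patch: Patch, control_points: int = 5, strength: float = 0.3,
                    rng: Optional[np.random.Generator] = None) -> Patch:
    """Random monotone remapping of [0, 1] onto itself.

    ``control_points`` uniformly spaced knots are jittered by up to
    ``strength`` of the knot spacing, sorted (preserving monotonicity) and
    pinned at 0 and 1; values are remapped through a monotone piecewise-cubic
    (PCHIP) interpolant, so the voxel intensity ordering is preserved.
    """
    if control_points < 3:
        raise ValueError("need at least 3 control points")
    if not patch.normalized:
        raise ValueError("histogram_shift expects a normalized patch")
    rng = np.random.default_rng(rng)
    x = np.linspace(0.0, 1.0, control_points)
    if strength == 0:
        return patch.copy_with(patch.values.copy())
    y = np.sort(x + strength * rng.uniform(-1.0, 1.0, size=control_points) / (control_points - 1))
    y = (y - y[0]) / (y[-1] - y[0])  # pin endpoints: 0 -> 0, 1 -> 1
    remap = PchipInterpolator(x, y)
    out = np.clip(remap(patch.values), 0.0, 1.0).astype(np.float32)
    return patch.copy_with(out)


def apply_view(patch: Patch, policy: AugmentationPolicy,
               rng: Optional[np.random.Generator] = None) -> Patch:
    """One stochastic augmented view of a normalized patch."""
    if not patch.normalized:
        raise ValueError("apply_view expects a normalized patch")
    rng = np.random.default_rng(rng)
    v = patch.values.astype(np.float32, copy=True)
    for name in policy.transforms:
        if name == "flip":
            for axis in range(3):
                if rng.random() < policy.flip_prob:
                    v = np.flip(v, axis=axis)
        elif name == "rot90":
            if rng.random() < policy.rotate_prob:
                axes = [(0, 1), (0, 2), (1, 2)][rng.integers(0, 3)]
                v = np.rot90(v, k=int(rng.integers(1, 4)), axes=axes)
        elif name == "rotate":
            if rng.random() < policy.rotate_prob:
                axes = [(0, 1), (0, 2), (1, 2)][rng.integers(0, 3)]
                angle = float(rng.uniform(-policy.free_rotate_max_deg, policy.free_rotate_max_deg))
                v = ndimage.rotate(v, angle, axes=axes, reshape=False, order=1,
                                   mode="constant", cval=0.0)
        elif name == "translate":
            t = policy.translate_voxels
            if t > 0:
                v = _translate(v, rng.integers(-t, t + 1, size=3))
        elif name == "crop_resize":
            scale = float(rng.uniform(*policy.crop_scale_range))
            v = _crop_resize(v, scale, rng)
        elif name == "blur":
            if rng.random() < policy.blur_prob:
                sigma = float(rng.uniform(*policy.blur_sigma_range))
                if sigma > 0.05:
                    v = ndimage.gaussian_filter(v, sigma=sigma)
        elif name == "noise":
            if policy.noise_sd > 0:
                v = v + rng.normal(0.0, policy.noise_sd, size=v.shape)
        elif name == "smooth_noise":
            if policy.smooth_noise_sd > 0:
                corr = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=v.shape),
                                               sigma=policy.smooth_noise_sigma)
                sd = corr.std()
                if sd > 0:
                    v = v + policy.smooth_noise_sd * corr / sd
        elif name == "hist_shift":
            tmp = histogram_shift(patch.copy_with(np.clip(v, 0, 1).astype(np.float32)),
                                  policy.hist_points, policy.hist_strength, rng)
            v = tmp.values
    v = np.clip(v, 0.0, 1.0).astype(np.float32)
    return patch.copy_with(np.ascontiguousarray(v))
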