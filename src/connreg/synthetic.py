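"""Synthetic fine-structure test images.

Generators for the three kinds of inputs the regularizers are studied on:

* solid binary blocks (for inspecting the pointwise kernel responses),
* thin straight lines with an optional central gap, drawn at low contrast
  over a mid-grey background with additive Gaussian noise — the regime of
  pavement-crack photographs, where a faint crack is broken into pieces by
  noise and the desired behaviour is to bridge the gap;
* branching trees of thin polylines whose contrast fades with depth,
  emulating retinal-vessel geometry.

Ground truth for the broken line is the *bridged* line: closing the gap is
the behaviour the connectivity regularizer exists to produce, so it must
score as true positive rather than as error. All generators are pure
functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

__all__ = [
    "SyntheticSample",
    "block_field",
    "broken_line",
    "branching_structure",
    "feature_map_from_sample",
]

BACKGROUND_LEVEL = 0.4  # mid-grey background; contrast <= ~0.4 keeps images "low contrast"

_ORIENTATIONS = ("horizontal", "vertical", "diag45", "diag135")


@dataclass(frozen=True)
class SyntheticSample:
    """A generated image with its exact ground-truth mask and metadata."""

    image: np.ndarray  # float in [0, 1], shape (H, W)
    gt: np.ndarray  # bool, shape (H, W)
    meta: dict = field(default_factory=dict)


def block_field(h: int, w: int, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Binary field with ones on an axis-aligned rectangle.

    ``rect`` is (top, left, height, width) and must lie inside the bounds.
    """
    top, left, rh, rw = rect
    if rh < 0 or rw < 0 or top < 0 or left < 0 or top + rh > h or left + rw > w:
        raise ValueError(f"rectangle {rect} does not fit inside ({h}, {w})")
    u = np.zeros((h, w), dtype=float)
    u[top : top + rh, left : left + rw] = 1.0
    return u


def _line_support(
    h: int, w: int, orientation: str, thickness: int
) -> tuple[np.ndarray, np.ndarray]:
    """Full (un-gapped) line mask plus the along-line coordinate of each pixel."""
    mask = np.zeros((h, w), dtype=bool)
    if orientation == "horizontal":
        r0 = h // 2 - thickness // 2
        mask[r0 : r0 + thickness, :] = True
        coord = np.broadcast_to(np.arange(w, dtype=float), (h, w))
    elif orientation == "vertical":
        c0 = w // 2 - thickness // 2
        mask[:, c0 : c0 + thickness] = True
        coord = np.broadcast_to(np.arange(h, dtype=float)[:, None], (h, w))
    elif orientation in ("diag45", "diag135"):
        if orientation == "diag45":
            rr, cc = _draw_line(0, 0, h - 1, w - 1)
        else:
            rr, cc = _draw_line(0, w - 1, h - 1, 0)
        base = np.zeros((h, w), dtype=bool)
        base[rr, cc] = True
        # thicken by stacking parallel one-pixel lines shifted across rows
        for k in range(thickness):
            shift = k - thickness // 2
            lo = max(0, shift)
            hi = min(h, h + shift)
            mask[lo:hi, :] |= base[lo - shift : hi - shift, :]
        coord = np.broadcast_to(np.arange(w, dtype=float), (h, w))
    else:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}, got {orientation!r}")
    return mask, np.asarray(coord, dtype=float)


def broken_line(
    h: int = 64,
    w: int = 64,
    orientation: str = "horizontal",
    gap: int = 2,
    thickness: int = 2,
    contrast: float = 0.3,
    noise_sigma: float = 0.05,
    seed: int = 0,
    background: float = BACKGROUND_LEVEL,
) -> SyntheticSample:
    """Thin straight line with a centered gap, at low contrast plus noise.

    The image carries the *gapped* line (background level inside the gap);
    the ground truth is the bridged line, so repairing the break counts as
    correct. Identical parameters and seed give bit-identical samples.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if thickness < 1:
        raise ValueError("thickness must be >= 1")
    if not 0 < contrast <= 1:
        raise ValueError("contrast must lie in (0, 1]")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    full, coord = _line_support(h, w, orientation, thickness)
    center = (coord[full].min() + coord[full].max()) / 2.0
    gap_mask = full & (np.abs(coord - center) < gap / 2.0 + 1e-9) if gap > 0 else np.zeros_like(full)
    visible = full & ~gap_mask
    rng = np.random.default_rng(seed)
    image = background + contrast * visible.astype(float)
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    meta = {
        "kind": "broken_line",
        "orientation": orientation,
        "gap": int(gap),
        "thickness": int(thickness),
        "contrast": float(contrast),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
        "background": float(background),
    }
    return SyntheticSample(image=image, gt=full, meta=meta)


def branching_structure(
    h: int = 64,
    w: int = 64,
    n_branches: int = 4,
    contrast: float = 0.3,
    noise_sigma: float = 0.05,
    seed: int = 0,
    background: float = BACKGROUND_LEVEL,
) -> SyntheticSample:
    """Seeded random tree of thin polylines with depth-fading contrast.

    Starts from a root on the left edge and grows ``n_branches`` segments,
    each branching off a previously drawn tip at a perturbed heading.
    Contrast decays by a factor 0.8 per generation, so the finest branches
    are the faintest — the situation in which thin structures get lost.
    Ground truth is the exact drawn support.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if not 0 < contrast <= 1:
        raise ValueError("contrast must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    intensity = np.zeros((h, w), dtype=float)
    gt = np.zeros((h, w), dtype=bool)
    # tips: (row, col, heading in radians, depth)
    tips: list[tuple[int, int, float, int]] = [(h // 2, 0, 0.0, 0)]
    for _ in range(n_branches):
        r, c, heading, depth = tips[rng.integers(len(tips))]
        heading = heading + rng.uniform(-0.7, 0.7)
        length = int(rng.integers(max(4, min(h, w) // 4), max(5, min(h, w) // 2)))
        r2 = int(np.clip(round(r + length * np.sin(heading)), 0, h - 1))
        c2 = int(np.clip(round(c + length * np.cos(heading)), 0, w - 1))
        rr, cc = _draw_line(r, c, r2, c2)
        width = int(rng.integers(1, 3))  # 1-2 px wide
        level = contrast * (0.8**depth)
        for k in range(width):
            rk = np.clip(rr + k, 0, h - 1)
            gt[rk, cc] = True
            intensity[rk, cc] = np.maximum(intensity[rk, cc], level)
        tips.append((r2, c2, heading, depth + 1))
    image = background + intensity
    if noise_sigma > 0:
        image = image + rng.normal(0.0, noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    meta = {
        "kind": "branching",
        "n_branches": int(n_branches),
        "contrast": float(contrast),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
        "background": float(background),
    }
    return SyntheticSample(image=image, gt=gt, meta=meta)


def feature_map_from_sample(sample: SyntheticSample, margin: float = 4.0) -> np.ndarray:
    """Two-channel score field standing in for a network's logits.

    Channel 0 (background) scores ``margin * (0.5 - image)``; channel 1
    (foreground) scores ``margin * (image - 0.5)``. The two channels are
    exact negatives, and ``margin`` controls how confident the resulting
    softmax probabilities are.
    """
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    img = np.asarray(sample.image, dtype=float)
    fg = margin * (img - 0.5)
    return np.stack([-fg, fg], axis=2)
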