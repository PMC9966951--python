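"""Convolution kernels and the regularization inner products they induce.

Two families of small stencils drive the regularizers in this package:

* a discrete Gaussian, whose soft-threshold-dynamics (STD) inner product
  ``<u, k * (1 - u)>`` approximates boundary length weighted by curvature;
* four directional two-point kernels (vertical, horizontal and the two
  diagonals), whose connectivity inner product ``<u, k * (-u)>`` rewards
  expanding the foreground preferentially along the chosen direction.

Both inner products are cheap (one convolution plus an elementwise product)
and smooth in ``u``, which is what makes them usable inside gradient-based
pipelines where total variation is awkward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Kernel",
    "gaussian_kernel",
    "directional_kernel",
    "convolve",
    "std_term",
    "connectivity_term",
    "std_response",
    "connectivity_response",
    "DIRECTIONS",
]

# The four directional stencils. Each places a weight of 0.5 on the two
# neighbours that straddle the centre along the named direction, so that
# (k * u) at a pixel averages the two opposite neighbours. "vertical" pairs
# the pixels above and below (it expands the foreground vertically);
# diag45 runs along the main image diagonal, diag135 along the anti-diagonal.
DIRECTIONS: dict[str, np.ndarray] = {
    "vertical": np.array([[0.0, 0.5, 0.0], [0.0, 0.0, 0.0], [0.0, 0.5, 0.0]]),
    "horizontal": np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.5], [0.0, 0.0, 0.0]]),
    "diag45": np.array([[0.5, 0.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.5]]),
    "diag135": np.array([[0.0, 0.0, 0.5], [0.0, 0.0, 0.0], [0.5, 0.0, 0.0]]),
}

_KINDS = ("gaussian", "vertical", "horizontal", "diag45", "diag135", "custom")


@dataclass(frozen=True)
class Kernel:
    """A small 2-D nonnegative stencil with odd side lengths.

    Parameters
    ----------
    weights : ndarray
        The stencil, stored read-only.
    kind : str
        One of ``gaussian``, ``vertical``, ``horizontal``, ``diag45``,
        ``diag135`` or ``custom``.
    sigma : float, optional
        Standard deviation in pixels; only meaningful for Gaussian kernels.
    """

    weights: np.ndarray
    kind: str = "custom"
    sigma: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("kernel weights must be a 2-D array")
        if w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError(f"kernel side lengths must be odd, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.kind == "gaussian":
            if not np.all(w > 0):
                raise ValueError("Gaussian kernel weights must be strictly positive")
            if abs(w.sum() - 1.0) > 1e-12:
                raise ValueError("Gaussian kernel must sum to 1 within 1e-12")
            if not np.allclose(w, w[::-1, ::-1], rtol=0, atol=1e-15):
                raise ValueError("Gaussian kernel must be 180-degree symmetric")
        elif self.kind in DIRECTIONS:
            if np.count_nonzero(w == 0.5) != 2 or np.count_nonzero(w) != 2:
                raise ValueError(
                    "directional kernel must have exactly two entries of 0.5"
                )
            if not np.array_equal(w, w[::-1, ::-1]):
                raise ValueError("directional kernel must be 180-degree symmetric")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def to_config(self) -> dict:
        """Serialize to a plain dict (round-trips through YAML/JSON)."""
        if self.kind == "gaussian":
            return {
                "kind": "gaussian",
                "size": int(self.shape[0]),
                "sigma": float(self.sigma),
            }
        if self.kind in DIRECTIONS:
            return {"kind": self.kind}
        return {"kind": "custom", "weights": self.weights.tolist()}

    @classmethod
    def from_config(cls, cfg: dict) -> "Kernel":
        kind = cfg.get("kind", "custom")
        if kind == "gaussian":
            return gaussian_kernel(int(cfg.get("size", 3)), float(cfg.get("sigma", 1.0)))
        if kind in DIRECTIONS:
            return directional_kernel(kind)
        return cls(np.asarray(cfg["weights"], dtype=float), kind="custom")


def gaussian_kernel(size: int = 3, sigma: float = 1.0) -> Kernel:
    """Sampled, normalized Gaussian stencil.

    ``weights[i, j]`` is proportional to ``exp(-(di^2 + dj^2) / (2 sigma^2))``
    at integer offsets ``(di, dj)`` from the centre, normalized to sum to 1.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError(f"size must be a positive odd integer, got {size}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    half = size // 2
    d = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(d**2) / (2.0 * sigma**2))
    w = np.outer(g1, g1)
    w /= w.sum()
    return Kernel(w, kind="gaussian", sigma=float(sigma))


def directional_kernel(direction: str) -> Kernel:
    """One of the four two-point directional stencils (3x3)."""
    if direction not in DIRECTIONS:
        raise ValueError(
            f"direction must be one of {sorted(DIRECTIONS)}, got {direction!r}"
        )
    return Kernel(DIRECTIONS[direction].copy(), kind=direction)


def directional_kernels() -> tuple[Kernel, Kernel, Kernel, Kernel]:
    """All four directional kernels, in (vertical, horizontal, diag45, diag135) order."""
    return tuple(directional_kernel(d) for d in ("vertical", "horizontal", "diag45", "diag135"))


def convolve(field: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Convolve a 2-D field with a kernel using reflect (symmetric) padding.

    Reflect padding avoids the spurious boundary-length signal that zero
    padding would create at the image border. All kernels here are symmetric
    under 180-degree rotation, so convolution equals correlation.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim != 2:
        raise ValueError("field must be 2-D")
    if not np.all(np.isfinite(field)):
        raise ValueError("field must be finite")
    return ndimage.convolve(field, kernel.weights, mode="reflect")


def _as_channels(u: np.ndarray) -> np.ndarray:
    """View a 2-D field as a single-channel stack (H, W, 1); pass 3-D through."""
    u = np.asarray(u, dtype=float)
    if u.ndim == 2:
        return u[:, :, None]
    if u.ndim == 3:
        return u
    raise ValueError("u must be 2-D (H, W) or 3-D (H, W, C)")


def _check_unit_range(u: np.ndarray) -> None:
    if u.min() < -1e-12 or u.max() > 1 + 1e-12:
        raise ValueError("u values must lie in [0, 1]")


def std_response(u: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Pointwise STD integrand ``u * (k * (1 - u))`` for a 2-D field.

    Nonzero only within one kernel radius of the region boundary; for a
    Gaussian kernel it is largest at corners, where curvature is highest.
    """
    u = np.asarray(u, dtype=float)
    _check_unit_range(u)
    return u * convolve(1.0 - u, kernel)


def connectivity_response(u: np.ndarray, kernel: Kernel) -> np.ndarray:
    """Pointwise connectivity integrand ``u * (k * (-u))`` for a 2-D field."""
    u = np.asarray(u, dtype=float)
    _check_unit_range(u)
    return u * convolve(-u, kernel)


def std_term(u: np.ndarray, kernel: Kernel) -> float:
    """Soft-threshold-dynamics regularizer ``<u, k * (1 - u)>``.

    For a multi-channel probability field the inner product is summed over
    all channels; a single 2-D (e.g. binary) field is treated as one channel.
    """
    stack = _as_channels(u)
    _check_unit_range(stack)
    total = 0.0
    for c in range(stack.shape[2]):
        total += float(np.sum(stack[:, :, c] * convolve(1.0 - stack[:, :, c], kernel)))
    return total


def connectivity_term(
    u: np.ndarray, kernel: Kernel, foreground_channels: tuple[int, ...] | None = None
) -> float:
    """Connectivity regularizer ``<u, k * (-u)>`` over the foreground channels.

    Always <= 0 for nonnegative kernels; more foreground makes it more
    negative, which is exactly the expansion pressure the term supplies.
    For a 2-D field the sum runs over that field. For a multi-channel field
    the default foreground set is every channel except channel 0 (the
    background convention used throughout the package).
    """
    stack = _as_channels(u)
    _check_unit_range(stack)
    if np.asarray(u).ndim == 2:
        channels: tuple[int, ...] = (0,)
    elif foreground_channels is None:
        channels = tuple(range(1, stack.shape[2]))
    else:
        channels = tuple(foreground_channels)
    total = 0.0
    for c in channels:
        total += float(np.sum(stack[:, :, c] * convolve(-stack[:, :, c], kernel)))
    return total
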