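"""En-face projection and stripe-artifact removal.

Angiographic volumes are collapsed to 2D by a maximum-intensity
projection over a dermal depth slab (default 40-440 um below the
surface). Motion artifacts, which appear as stripes along the fast scan
axis, are suppressed with the combined wavelet-Fourier filter: at each
level of a multilevel wavelet decomposition, the detail band oriented
with the stripes is Fourier-transformed along the stripe direction and
its near-zero-frequency coefficients are damped with a Gaussian notch
1 - exp(-k^2 / (2 sigma^2)) before reconstruction.
"""

from __future__ import annotations

import numpy as np
import pywt

from .images import AngioVolume, EnFaceImage


def project_enface(
    volume: AngioVolume,
    depth_range_um: tuple[float, float] = (40.0, 440.0),
    state: str = "baseline",
) -> EnFaceImage:
    """Maximum-intensity projection over the half-open depth slab [low, high).

    Depth is measured from the first slice of the volume; slice i sits at
    depth i * dz. An empty slab is an error.
    """
    low, high = depth_range_um
    if not low < high:
        raise ValueError("depth range must satisfy low < high")
    _, _, dz = volume.spacing_um
    n = volume.voxels.shape[0]
    depths = np.arange(n) * dz
    sel = (depths >= low) & (depths < high)
    if not sel.any():
        raise ValueError(
            f"depth slab [{low}, {high}) um selects no slices "
            f"(volume spans 0-{depths[-1]:.1f} um)"
        )
    pixels = volume.voxels[sel].max(axis=0)
    return EnFaceImage(pixels, pixel_pitch_um=volume.lateral_pitch_um, state=state)


def _damp_band(coeffs: np.ndarray, damping_sigma: float) -> np.ndarray:
    """Gaussian-notch the near-zero frequencies along axis 0 of a band."""
    f = np.fft.fftshift(np.fft.fft(coeffs, axis=0), axes=0)
    n = coeffs.shape[0]
    k = np.arange(n) - n // 2
    damp = 1.0 - np.exp(-(k**2) / (2.0 * damping_sigma**2))
    f *= damp[:, None]
    return np.fft.ifft(np.fft.ifftshift(f, axes=0), axis=0).real


def destripe_array(
    pixels: np.ndarray,
    levels: int = 5,
    wavelet: str = "db4",
    damping_sigma: float = 2.4,
    stripe_axis: str = "fast",
) -> np.ndarray:
    """Wavelet-Fourier destriping of a raw 2D array.

    ``stripe_axis="fast"`` removes stripes that are constant within each
    column (the offset varying across columns); "slow" removes the
    transposed pattern. Output is clipped to be non-negative.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    pixels = np.asarray(pixels, dtype=np.float64)
    if min(pixels.shape) < 2**levels:
        raise ValueError(
            f"image of shape {pixels.shape} is too small for {levels} "
            "decomposition levels"
        )
    transposed = stripe_axis == "slow"
    if stripe_axis not in ("fast", "slow"):
        raise ValueError("stripe_axis must be 'fast' or 'slow'")
    work = pixels.T if transposed else pixels

    approx = work
    details = []
    for _ in range(levels):
        approx, (ch, cv, cd) = pywt.dwt2(approx, wavelet)
        details.append((ch, cv, cd))

    out = approx
    for ch, cv, cd in reversed(details):
        # stripes constant along axis 0 live in the band that is high-pass
        # across columns and low-pass down rows; notch its k~0 rows
        cv = _damp_band(cv, damping_sigma)
        out = out[: ch.shape[0], : ch.shape[1]]
        out = pywt.idwt2((out, (ch, cv, cd)), wavelet)

    out = out[: work.shape[0], : work.shape[1]]
    if transposed:
        out = out.T
    return np.clip(out, 0.0, None)


def remove_stripes(
    image: EnFaceImage,
    levels: int = 5,
    wavelet: str = "db4",
    damping_sigma: float = 2.4,
    stripe_axis: str = "fast",
) -> EnFaceImage:
    """Destripe an en-face image (see :func:`destripe_array`)."""
    return image.with_pixels(
        destripe_array(image.pixels, levels, wavelet, damping_sigma, stripe_axis)
    )


def stripe_band_energy(pixels: np.ndarray, stripe_axis: str = "fast") -> float:
    """Energy of the stripe pattern: variance of per-line means x pixels.

    For the "fast" convention stripes are constant within columns, so the
    stripe energy is the variance of column means summed over the image.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    means = pixels.mean(axis=0) if stripe_axis == "fast" else pixels.mean(axis=1)
    return float(np.var(means) * pixels.size)
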