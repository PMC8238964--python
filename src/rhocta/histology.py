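"""Serial-section registration and projection.

Horizontal histology sections drift laterally during collection; each
section is aligned to its predecessor with integer-precision
phase-correlation translation, chained cumulatively back to the first
section, and the registered stack is collapsed with a per-pixel maximum
intensity projection so histology enters the same segmentation/metrics
chain as the angiographic images.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from skimage.registration import phase_cross_correlation

from .images import EnFaceImage, HistologyStack


def register_sections(stack: HistologyStack, max_shift_px: int = 10) -> HistologyStack:
    """Translation-register each section to its predecessor.

    Shifts are estimated by phase correlation at integer precision and
    chained (section i is corrected by the cumulative shift back to
    section 1), with each per-step shift clipped to ``max_shift_px``.
    A flat (zero-variance) section cannot be registered; it gets shift
    (0, 0) with a warning. Applied shifts are recorded on the result.
    """
    if stack.n_sections < 2:
        raise ValueError("registration needs at least 2 sections")
    sections = stack.sections
    shifts = np.zeros((stack.n_sections, 2), dtype=int)
    registered = np.empty_like(sections)
    registered[0] = sections[0]
    prev = sections[0]
    for i in range(1, stack.n_sections):
        cur = sections[i]
        if np.ptp(cur) == 0 or np.ptp(prev) == 0:
            warnings.warn(
                f"section {i} (or its predecessor) is flat; assuming zero shift",
                stacklevel=2,
            )
            shift = np.zeros(2, dtype=int)
        else:
            # prev is already in the section-1 frame, so the estimated
            # translation is the full chained correction for this section
            est, _, _ = phase_cross_correlation(prev, cur, upsample_factor=1)
            shift = np.clip(np.round(est).astype(int), -max_shift_px, max_shift_px)
        shifts[i] = shift
        registered[i] = _translate(cur, shift, fill=float(np.min(cur)))
        prev = registered[i]
    return replace(stack, sections=registered, applied_shifts=shifts)


def _translate(img: np.ndarray, shift: np.ndarray, fill: float) -> np.ndarray:
    dy, dx = int(shift[0]), int(shift[1])
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def max_intensity_project(stack: HistologyStack) -> EnFaceImage:
    """Per-pixel maximum over all sections; state = histology."""
    pixels = stack.sections.max(axis=0)
    return EnFaceImage(
        pixels, pixel_pitch_um=stack.pixel_pitch_um, state="histology", site=stack.site
    )
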