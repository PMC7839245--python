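"""Lung aeration quantification and mean-linear-intercept morphometry.

Aeration: on a fluoroscopy-like grayscale frame, radiolucent (dark) pixels
inside the lung region count as aerated; hourly counts are expressed as
percent change versus the baseline frame (H0).  The study's segmentation was
manual; here the threshold is either fixed or Otsu's, and always recorded.

Morphometry: the mean linear intercept (MLI) lays evenly spaced test lines
over a binary airspace mask, measures the air chords they cut (excluding
regions under an exclusion mask — vessels and large airways — and chords
truncated by the image edge), and reports total air length over the number of
complete air chords, in micrometres.  MLI grows with emphysematous airspace
enlargement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "AerationResult",
    "MorphometryResult",
    "segment_lung",
    "aeration_change",
    "mean_linear_intercept",
    "mli_fields",
]


@dataclass
class AerationResult:
    """Aerated-area measurement for one timepoint."""

    timepoint: str
    aerated_pixels: int
    region_pixels: int
    pct_change_vs_h0: float = float("nan")

    def __post_init__(self) -> None:
        if self.aerated_pixels > self.region_pixels:
            raise ValueError("aerated pixels cannot exceed the region")
        if self.aerated_pixels < 0 or self.region_pixels <= 0:
            raise ValueError("pixel counts must be non-negative (region > 0)")


@dataclass
class MorphometryResult:
    """Mean linear intercept over one field or averaged over fields."""

    mli: float              # micrometres
    n_lines: int
    n_intercepts: int       # complete air chords counted
    pixel_size: float       # micrometres per pixel
    fields_used: int = 1

    def __post_init__(self) -> None:
        if self.mli <= 0 or self.n_intercepts <= 0:
            raise ValueError("degenerate morphometry result")


# ---------------------------------------------------------------------------
# aeration
# ---------------------------------------------------------------------------

def segment_lung(frame: np.ndarray, threshold="otsu",
                 region_mask: np.ndarray | None = None,
                 ) -> tuple[np.ndarray, int, float]:
    """Count aerated (radiolucent) pixels inside the lung region.

    Pixels strictly darker than ``threshold`` count as aerated; ``"otsu"``
    picks the threshold automatically from the intensity histogram of the
    region.  Returns ``(aerated mask, aerated pixel count, threshold used)``
    so the choice is always recorded.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel image")
    if region_mask is None:
        region_mask = np.ones(frame.shape, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != frame.shape:
        raise ValueError("region mask shape mismatch")
    vals = frame[region_mask]
    if vals.size == 0:
        raise ValueError("empty lung region")
    thr = float(threshold_otsu(vals)) if threshold == "otsu" else float(threshold)
    aerated = (frame < thr) & region_mask
    return aerated, int(aerated.sum()), thr


def aeration_change(series: list[AerationResult]) -> list[AerationResult]:
    """Percent change of aerated area versus the first (H0) timepoint.

    ``change_t = 100 * (aerated_t - aerated_H0) / aerated_H0``; H0 itself is
    0 by construction.  Results are returned with ``pct_change_vs_h0`` filled.
    """
    if not series:
        raise ValueError("empty series")
    base = series[0].aerated_pixels
    if base == 0:
        raise ValueError("zero aerated area at baseline; change undefined")
    out = []
    for r in series:
        pct = 100.0 * (r.aerated_pixels - base) / base
        out.append(AerationResult(r.timepoint, r.aerated_pixels,
                                  r.region_pixels, pct))
    return out


# ---------------------------------------------------------------------------
# mean linear intercept
# ---------------------------------------------------------------------------

def _line_chords(air_line: np.ndarray, valid_line: np.ndarray) -> tuple[list[int], bool]:
    """Complete air-chord lengths along one test line.

    A chord is complete when bounded by tissue on both sides within a valid
    stretch; chords touching the line ends or an exclusion boundary are
    dropped (truncation bias).  Returns the chord lengths and whether the
    line met any tissue at all.
    """
    chords: list[int] = []
    saw_tissue = False
    n = len(air_line)
    i = 0
    while i < n:
        if not valid_line[i]:
            i += 1
            continue
        j = i
        while j < n and valid_line[j]:
            j += 1
        seg = air_line[i:j]
        if (~seg).any():
            saw_tissue = True
        # runs of air within the valid stretch
        k = 0
        m = len(seg)
        while k < m:
            if seg[k]:
                k2 = k
                while k2 < m and seg[k2]:
                    k2 += 1
                if k > 0 and k2 < m:   # bounded by tissue on both sides
                    chords.append(k2 - k)
                k = k2
            else:
                k += 1
        i = j
    return chords, saw_tissue


def mean_linear_intercept(air_mask: np.ndarray,
                          exclusion_mask: np.ndarray | None = None,
                          spacing: int = 20,
                          orientation: str = "horizontal",
                          pixel_size: float = 1.0,
                          denominator: str = "air_chords") -> MorphometryResult:
    """Mean linear intercept of a binary airspace mask, in micrometres.

    Evenly spaced test lines (every ``spacing`` pixels; ``orientation`` is
    ``horizontal``, ``vertical`` or ``both``) cut chords through the air
    phase.  Pixels under ``exclusion_mask`` (vessels, large airways) are
    ignored.  With the default convention, MLI = total air-chord length /
    number of complete air chords; ``denominator="line_length"`` uses the
    classical total-test-line-length over air-chord-count convention instead.
    """
    air = np.asarray(air_mask, dtype=bool)
    if air.ndim != 2:
        raise ValueError("air_mask must be 2-D")
    if exclusion_mask is None:
        excl = np.zeros_like(air)
    else:
        excl = np.asarray(exclusion_mask, dtype=bool)
        if excl.shape != air.shape:
            raise ValueError("masks must share one shape")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if orientation not in ("horizontal", "vertical", "both"):
        raise ValueError("orientation must be horizontal, vertical or both")

    lines: list[tuple[np.ndarray, np.ndarray]] = []
    if orientation in ("horizontal", "both"):
        for r in range(spacing // 2, air.shape[0], spacing):
            lines.append((air[r, :], ~excl[r, :]))
    if orientation in ("vertical", "both"):
        for c in range(spacing // 2, air.shape[1], spacing):
            lines.append((air[:, c], ~excl[:, c]))

    chords: list[int] = []
    usable_lines = 0
    valid_len = 0
    for air_line, valid_line in lines:
        cs, saw_tissue = _line_chords(air_line, valid_line)
        if not saw_tissue:
            continue  # all-air line: no intercepts, excluded as degenerate
        usable_lines += 1
        valid_len += int(valid_line.sum())
        chords.extend(cs)
    if not chords:
        raise ValueError("no complete air chords on any test line "
                         "(degenerate field)")
    if denominator == "air_chords":
        mli = pixel_size * sum(chords) / len(chords)
    elif denominator == "line_length":
        mli = pixel_size * valid_len / len(chords)
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    return MorphometryResult(mli=mli, n_lines=usable_lines,
                             n_intercepts=len(chords), pixel_size=pixel_size)


def mli_fields(masks: list[np.ndarray],
               exclusion_masks: list[np.ndarray] | None = None,
               **kwargs) -> MorphometryResult:
    """Average MLI over multiple microscopy fields (18 per subject in the
    study protocol)."""
    if not masks:
        raise ValueError("need at least one field")
    if exclusion_masks is None:
        exclusion_masks = [None] * len(masks)
    results = [mean_linear_intercept(m, e, **kwargs)
               for m, e in zip(masks, exclusion_masks)]
    return MorphometryResult(
        mli=float(np.mean([r.mli for r in results])),
        n_lines=sum(r.n_lines for r in results),
        n_intercepts=sum(r.n_intercepts for r in results),
        pixel_size=results[0].pixel_size,
        fields_used=len(results))
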