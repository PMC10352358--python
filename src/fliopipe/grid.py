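"""ETDRS macular grid masks and regional reduction of lifetime maps.

The ETDRS grid consists of three concentric rings of diameter 1, 3 and
6 mm centred on the fovea: the central subfield (C), an inner ring and an
outer ring, each ring split into nasal (N), superior (S), temporal (T) and
inferior (I) quadrants by the two 45-degree diagonals.  The nine subfields
are labelled C, N1/S1/T1/I1 (inner) and N2/S2/T2/I2 (outer); IR and OR
denote the pooled inner- and outer-ring aggregates.

Nasal/temporal orientation mirrors between eyes: for a right eye (OD)
image, temporal is image-left and nasal image-right; for OS the convention
is mirrored.  This orientation is a convention of this package and is
configurable where it matters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EtdrsMasks", "build_grid_masks", "regional_summary", "SUBFIELDS", "REGIONS"]

logger = logging.getLogger(__name__)

#: The nine disjoint subfields, in label order (label 1..9 in the label image).
SUBFIELDS = ("C", "N1", "S1", "T1", "I1", "N2", "S2", "T2", "I2")
#: Subfields plus the pooled ring aggregates reported by FLIO-reader.
REGIONS = SUBFIELDS + ("IR", "OR")

_LABELS = {name: i + 1 for i, name in enumerate(SUBFIELDS)}
OUTSIDE = 0

# Ring radii in mm (diameters 1 / 3 / 6 mm).
R_CENTER = 0.5
R_INNER = 1.5
R_OUTER = 3.0


@dataclass
class EtdrsMasks:
    """Label image for the nine ETDRS subfields plus helpers.

    ``labels`` holds 0 outside the 6 mm disc and the 1-based subfield label
    inside; ``center`` is the foveal pixel (row, col); ``laterality`` is
    "OD" or "OS".
    """

    labels: np.ndarray
    center: tuple[float, float]
    mm_per_pixel: float
    laterality: str

    def mask(self, region: str) -> np.ndarray:
        """Boolean mask for a subfield or an aggregate (IR, OR, grid)."""
        if region in _LABELS:
            return self.labels == _LABELS[region]
        if region == "IR":
            return np.isin(self.labels, [_LABELS[r] for r in ("N1", "S1", "T1", "I1")])
        if region == "OR":
            return np.isin(self.labels, [_LABELS[r] for r in ("N2", "S2", "T2", "I2")])
        if region == "grid":
            return self.labels != OUTSIDE
        raise KeyError(f"unknown region {region!r}")


def build_grid_masks(
    center: tuple[float, float],
    mm_per_pixel: float,
    shape: tuple[int, int],
    laterality: str = "OD",
) -> EtdrsMasks:
    """Build ETDRS subfield masks centred on the fovea.

    Membership is decided by the pixel-centre distance to the grid centre:
    C for r < 0.5 mm, inner ring for 0.5 <= r < 1.5 mm, outer ring for
    1.5 <= r < 3 mm.  Quadrants are split at the 45-degree diagonals;
    pixels exactly on a diagonal are assigned to the clockwise-first
    quadrant (S, then T, then I, then N in OD orientation) so ties are
    deterministic.

    Raises a ValueError if the 6 mm disc does not fit in the image.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be 'OD' or 'OS'")
    if mm_per_pixel <= 0:
        raise ValueError("mm_per_pixel must be positive")
    h, w = shape
    cy, cx = center
    r_pix = R_OUTER / mm_per_pixel
    if cy - r_pix < -0.5 or cx - r_pix < -0.5 or cy + r_pix > h - 0.5 or cx + r_pix > w - 0.5:
        raise ValueError(
            f"6 mm ETDRS disc (radius {r_pix:.1f} px) exceeds image bounds "
            f"{shape} at center {center}"
        )

    rows = np.arange(h)[:, None] - cy
    cols = np.arange(w)[None, :] - cx
    r_mm = np.hypot(rows, cols) * mm_per_pixel

    # Quadrants: superior is up (-row), inferior down; temporal/nasal depend
    # on laterality.  A pixel is in the vertical quadrants (S/I) when
    # |dy| > |dx|, horizontal when |dx| > |dy|; the tie |dx| == |dy| goes to
    # the quadrant that comes first clockwise from superior.
    dy, dx = rows, np.broadcast_to(cols, (h, w))
    dy = np.broadcast_to(dy, (h, w))
    vertical = np.abs(dy) >= np.abs(dx)  # ties -> vertical (S/I), clockwise-first
    superior = vertical & (dy <= 0)
    inferior = vertical & (dy > 0)
    right = ~vertical & (dx > 0)
    left = ~vertical & (dx < 0)
    if laterality == "OD":
        nasal, temporal = right, left
    else:
        nasal, temporal = left, right

    labels = np.zeros(shape, dtype=np.uint8)
    labels[r_mm < R_CENTER] = _LABELS["C"]
    inner = (r_mm >= R_CENTER) & (r_mm < R_INNER)
    outer = (r_mm >= R_INNER) & (r_mm < R_OUTER)
    for ring, suffix in ((inner, "1"), (outer, "2")):
        labels[ring & nasal] = _LABELS["N" + suffix]
        labels[ring & superior] = _LABELS["S" + suffix]
        labels[ring & temporal] = _LABELS["T" + suffix]
        labels[ring & inferior] = _LABELS["I" + suffix]

    return EtdrsMasks(labels=labels, center=(cy, cx), mm_per_pixel=mm_per_pixel, laterality=laterality)


def regional_summary(
    maps: dict[str, np.ndarray],
    masks: EtdrsMasks,
    valid: np.ndarray | None = None,
    subject: str = "",
    eye: str = "",
    channel: str = "",
) -> pd.DataFrame:
    """Reduce per-pixel parameter maps to per-region means and SDs.

    ``maps`` maps parameter names (e.g. ``tau_m``) to images; ``valid``
    optionally masks out non-converged or low-signal pixels, which are
    excluded (not zero-filled).  IR and OR are computed over the pooled
    member pixels of their four subfields, not as a mean of subfield means.

    Returns a tidy frame with columns subject, eye, channel, region,
    parameter, mean, sd, n_pixels.  Regions with no valid pixel are
    reported as missing (NaN mean, n_pixels 0) with a warning.
    """
    shape = masks.labels.shape
    rows = []
    for name, img in maps.items():
        img = np.asarray(img, dtype=float)
        if img.shape != shape:
            raise ValueError(f"map {name!r} shape {img.shape} != mask shape {shape}")
        ok = np.isfinite(img)
        if valid is not None:
            ok &= np.asarray(valid, dtype=bool)
        for region in REGIONS:
            sel = masks.mask(region) & ok
            n = int(sel.sum())
            if n == 0:
                warnings.warn(f"region {region} has no valid pixels for {name}", stacklevel=2)
                logger.warning("region %s has no valid pixels for %s", region, name)
                mean, sd = np.nan, np.nan
            else:
                vals = img[sel]
                mean = float(vals.mean())
                sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            rows.append(
                dict(
                    subject=subject, eye=eye, channel=channel, region=region,
                    parameter=name, mean=mean, sd=sd, n_pixels=n,
                )
            )
    return pd.DataFrame(rows)
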