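"""Fractional MT enhancement: voxelwise MT / non-MT ratio map.

Dividing the MT-prepared acquisition by the resolution-matched non-MT
acquisition cancels receive-field and proton-density variation and leaves a
dimensionless map in which macromolecule-rich tissue is suppressed (ratio
well below 1), fluid sits near 1, and neuromelanin-rich nuclei fall in
between — locally hyper-intense against the surrounding white matter of the
pons, which is what makes the locus coeruleus visible.

Voxels whose non-MT signal is at or below ``min_denominator`` (background
air, by default 5% of the robust non-MT maximum) are excluded: their ratio
is numerically unstable and carries no tissue information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import BinaryMask, VolumeGrid, require_same_grid


@dataclass
class EnhancementMap:
    """Dimensionless MT/non-MT ratio with an explicit validity mask.

    ``values.data`` is NaN exactly where ``valid_mask`` is False.
    """

    values: VolumeGrid
    valid_mask: BinaryMask

    @property
    def affine(self) -> np.ndarray:
        return self.values.affine

    @property
    def shape(self):
        return self.values.shape

    def valid_values(self) -> np.ndarray:
        """1-D array of the ratio at valid voxels."""
        return self.values.data[self.valid_mask.data]


def default_min_denominator(nomt: VolumeGrid, fraction: float = 0.05) -> float:
    """5% of the 99th-percentile non-MT intensity (robust maximum)."""
    return fraction * float(np.nanpercentile(nomt.data, 99.0))


def compute_enhancement(mt: VolumeGrid, nomt: VolumeGrid,
                        min_denominator: float | None = None) -> EnhancementMap:
    """Divide the MT by the non-MT volume, masking unstable denominators.

    Parameters
    ----------
    mt, nomt : VolumeGrid
        Paired acquisitions on one grid (checked; mismatch raises
        :class:`~lcmap.errors.GridMismatchError`).
    min_denominator : float, optional
        Voxels with ``nomt <= min_denominator`` are invalid (NaN).  Default:
        :func:`default_min_denominator` of the non-MT volume.

    Returns
    -------
    EnhancementMap
    """
    require_same_grid(mt, nomt, what="MT and non-MT volumes")
    if min_denominator is None:
        min_denominator = default_min_denominator(nomt)
    if min_denominator < 0:
        raise ValueError("min_denominator must be >= 0")
    valid = np.isfinite(nomt.data) & np.isfinite(mt.data) & (nomt.data > min_denominator)
    out = np.full(mt.shape, np.nan, dtype=np.float64)
    np.divide(mt.data, nomt.data, out=out, where=valid)
    values = VolumeGrid(data=out, affine=mt.affine)
    mask = BinaryMask(data=valid, affine=mt.affine, label="enhancement_valid")
    return EnhancementMap(values=values, valid_mask=mask)
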