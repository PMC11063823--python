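"""Normalized vector-sum tuning and the direction-selectivity index.

The per-ROI (and per-pixel) tuning measure used throughout the package:
responses :math:`R_n \\ge 0` at equally spaced directions
:math:`\\theta_n` are summed as unit vectors weighted by response,

.. math::

    \\vec R = \\frac{\\sum_n R_n(\\cos\\theta_n, \\sin\\theta_n)}{\\sum_n R_n},

whose angle is the preferred direction and whose length (in [0, 1] for
nonnegative responses) is the tuning magnitude.  The direction
selectivity index compares the response in the direction bin nearest
the vector-sum angle (pref) with the bin 180° away (null):

.. math::

    \\mathrm{DSI} = \\frac{R_\\mathrm{pref} - R_\\mathrm{null}}
                         {R_\\mathrm{pref} + R_\\mathrm{null}}.

Everything here is written batch-first (leading axes broadcast) so the
permutation test and the per-pixel map reuse one code path.
"""

from __future__ import annotations

import numpy as np

#: Sentinel angle reported where the vector sum is undefined (zero total).
UNDEFINED_ANGLE = np.nan


def vector_sum(responses: np.ndarray, directions_deg: np.ndarray):
    """Normalized vector sum over the last axis.

    Parameters
    ----------
    responses : array, shape (..., n_directions)
        Nonnegative per-direction responses (trial means).
    directions_deg : array, shape (n_directions,)

    Returns
    -------
    magnitude : array, shape (...)
        ``|sum R_n u_n| / sum R_n``; 0 where the denominator is <= 0.
    angle_deg : array, shape (...)
        Vector-sum angle in [0, 360); NaN where undefined.
    """
    responses = np.asarray(responses, dtype=float)
    theta = np.deg2rad(np.asarray(directions_deg, dtype=float))
    rx = np.sum(responses * np.cos(theta), axis=-1)
    ry = np.sum(responses * np.sin(theta), axis=-1)
    rt = np.sum(responses, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.hypot(rx, ry) / rt
    angle = np.rad2deg(np.arctan2(ry, rx)) % 360.0
    bad = ~(rt > 0)
    mag = np.where(bad, 0.0, mag)
    angle = np.where(bad, UNDEFINED_ANGLE, angle)
    return mag, angle


def nearest_direction_bin(angle_deg, directions_deg: np.ndarray):
    """Index of the direction bin circularly nearest each angle.

    Ties (angle exactly between two bins) resolve to the smaller angle,
    which for sorted ``directions_deg`` is the smaller index.
    """
    angle_deg = np.asarray(angle_deg, dtype=float)
    directions = np.asarray(directions_deg, dtype=float)
    diff = np.abs(((angle_deg[..., None] - directions) + 180.0) % 360.0 - 180.0)
    # argmin takes the first minimum -> smaller direction on exact ties
    return np.argmin(np.round(diff, 9), axis=-1)


def dsi(responses: np.ndarray, directions_deg: np.ndarray,
        preferred_angle_deg=None):
    """Direction selectivity index from per-direction responses.

    Parameters
    ----------
    responses : array, shape (..., n_directions)
    directions_deg : array, shape (n_directions,)
    preferred_angle_deg : array or None
        Vector-sum angle; recomputed when None.

    Returns
    -------
    dsi : array, shape (...)
        ``(R_pref - R_null) / (R_pref + R_null)``; 0 (degenerate) where
        the denominator is <= 0 or the preferred angle is undefined.
    pref_bin, null_bin : integer arrays
        Direction-bin indices used.
    """
    responses = np.asarray(responses, dtype=float)
    directions = np.asarray(directions_deg, dtype=float)
    n_dir = directions.shape[0]
    if preferred_angle_deg is None:
        _, preferred_angle_deg = vector_sum(responses, directions)
    pref_angle = np.asarray(preferred_angle_deg, dtype=float)
    defined = np.isfinite(pref_angle)
    pref_bin = nearest_direction_bin(np.where(defined, pref_angle, 0.0),
                                     directions)
    # exact 180 deg partner exists for even, equally spaced grids;
    # otherwise fall back to the bin nearest pref + 180
    if n_dir % 2 == 0 and _equally_spaced(directions):
        null_bin = (pref_bin + n_dir // 2) % n_dir
    else:
        null_angle = (np.take(directions, pref_bin) + 180.0) % 360.0
        null_bin = nearest_direction_bin(null_angle, directions)
    r_pref = np.take_along_axis(responses, pref_bin[..., None], axis=-1)[..., 0]
    r_null = np.take_along_axis(responses, null_bin[..., None], axis=-1)[..., 0]
    denom = r_pref + r_null
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (r_pref - r_null) / denom
    out = np.where((denom > 0) & defined, out, 0.0)
    return out, pref_bin, null_bin


def _equally_spaced(directions: np.ndarray, tol: float = 1e-9) -> bool:
    if directions.size < 2:
        return False
    step = 360.0 / directions.size
    expected = directions[0] + step * np.arange(directions.size)
    return bool(np.allclose(directions, expected, atol=tol))
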