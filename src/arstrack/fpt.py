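"""First passage time profiles along equal-distance resampled paths.

First passage time (FPT) at radius r, for a vertex v, is the time the
trajectory spends inside the circle of radius r centred on v, measured from
the last crossing of the circle before v to the first crossing after v
(backward + forward passage).  High FPT at a given radius marks restricted
search at that spatial scale.  Crossing instants are interpolated linearly
along the leg on which the circle is crossed.  Vertices whose circle is
never exited backward (track starts inside) or forward (track ends inside)
get NaN — the border effect, whose width grows with the radius.
"""

from __future__ import annotations

import numpy as np

from .preprocess import haversine_km
from .tracks import FPTSeries, ResampledPath


def pairwise_distances(path: ResampledPath) -> np.ndarray:
    """Dense vertex-to-vertex great-circle distance matrix (km).

    One FPT profile per radius needs the same matrix, so computing it once
    per path and passing it to :func:`compute_fpt` avoids the dominant
    cost of a radius ladder.
    """
    lat, lon = path.lat, path.lon
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


def compute_fpt(
    path: ResampledPath,
    radius_km: float,
    distances: np.ndarray | None = None,
) -> FPTSeries:
    """Per-vertex first passage time (hours) for one radius.

    NaN where either the backward or the forward crossing does not exist
    within the track.  ``distances`` may carry the precomputed output of
    :func:`pairwise_distances`.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    n = len(path)
    if n < 2:
        raise ValueError("path needs at least 2 vertices")
    D = pairwise_distances(path) if distances is None else distances
    hours = path.hours
    out = D > radius_km
    values = np.full(n, np.nan)
    for i in range(n):
        row_out = out[i]
        d = D[i]

        fwd = row_out[i + 1 :]
        if not fwd.any():
            continue
        jf = i + 1 + int(np.argmax(fwd))
        f = (radius_km - d[jf - 1]) / (d[jf] - d[jf - 1])
        t_fwd = hours[jf - 1] + f * (hours[jf] - hours[jf - 1])

        bwd = row_out[:i]
        if not bwd.any():
            continue
        jb = int(len(bwd) - 1 - np.argmax(bwd[::-1]))
        f = (radius_km - d[jb + 1]) / (d[jb] - d[jb + 1])
        t_bwd = hours[jb + 1] - f * (hours[jb + 1] - hours[jb])

        values[i] = t_fwd - t_bwd
    return FPTSeries(radius_km=radius_km, values=values, path=path)


def longest_defined_run(values: np.ndarray) -> tuple[int, int]:
    """Bounds (start, end inclusive) of the longest contiguous non-NaN run.

    Returns ``(-1, -1)`` when every value is NaN.  FPT border effects leave
    NaN at both ends of a profile; segmentation operates on this interior run.
    """
    defined = ~np.isnan(values)
    if not defined.any():
        return (-1, -1)
    padded = np.concatenate([[0], defined.astype(int), [0]])
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    best = int(np.argmax(ends - starts))
    return int(starts[best]), int(ends[best])
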