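"""Two-point LOD linkage analysis and genome-wide heat maps.

In a BC1 every call is fully informative, so the two-point likelihood is the
binomial likelihood of the recombinant count.  With ``R`` recombinants among
``n`` pairwise-complete individuals and ``r = min(R/n, 0.5)``::

    LOD = R log10(2 r) + (n - R) log10(2 (1 - r))

with the convention ``0 * log10(0) = 0`` (complete linkage gives
``n log10 2``).  Estimates above 0.5 are clamped: repulsion has no
expectation in a backcross, only sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from invcross.io import HET, MISSING, REC, GenotypeMatrix, MarkerMap


def two_point_lod(recombinants: int, informative: int) -> tuple[float, float]:
    """Return ``(r_hat, LOD)`` for one marker pair."""
    if informative <= 0:
        raise ValueError("informative count must be positive")
    if not 0 <= recombinants <= informative:
        raise ValueError("recombinant count must lie in [0, informative]")
    r = min(recombinants / informative, 0.5)
    lod = 0.0
    if recombinants > 0:
        lod += recombinants * np.log10(2 * r)
    if recombinants < informative:
        lod += (informative - recombinants) * np.log10(2 * (1 - r))
    return r, float(lod)


@dataclass
class LODMatrix:
    """Symmetric pairwise linkage summaries over all map markers."""

    marker_map: MarkerMap
    lod: np.ndarray
    r_hat: np.ndarray
    n_inf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        ids = self.marker_map.marker_ids
        return pd.DataFrame(self.lod, index=ids, columns=ids)


def lod_heatmap(genotypes: GenotypeMatrix) -> LODMatrix:
    """Two-point LOD for every unordered marker pair (pairwise deletion).

    Pairs with no pairwise-complete individual are NaN.  The diagonal is NaN.
    """
    calls = genotypes.calls
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    het = (calls == HET).astype(np.float64)
    rec = (calls == REC).astype(np.float64)
    valid = (calls != MISSING).astype(np.float64)
    n_inf = valid.T @ valid
    agree = het.T @ het + rec.T @ rec
    n_rec = n_inf - agree
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
        r_c = np.minimum(r, 0.5)
        lod = np.where(
            n_inf > 0,
            _xlog10(n_rec, 2 * r_c) + _xlog10(n_inf - n_rec, 2 * (1 - r_c)),
            np.nan,
        )
    np.fill_diagonal(lod, np.nan)
    np.fill_diagonal(r_c, np.nan)
    return LODMatrix(genotypes.marker_map, lod=lod, r_hat=r_c, n_inf=n_inf.astype(int))


def _xlog10(weight: np.ndarray, x: np.ndarray) -> np.ndarray:
    """weight * log10(x) with 0 * log10(0) == 0."""
    out = np.zeros(np.broadcast(weight, x).shape)
    mask = weight > 0
    out[mask] = weight[mask] * np.log10(np.where(mask, x, 1.0))[mask]
    return out


def flag_anomalous_linkage(
    matrix: LODMatrix,
    lod_threshold: float = 5.0,
    dist_threshold_mbp: float = 10.0,
    r_max: float = 0.25,
) -> pd.DataFrame:
    """Flag marker pairs with unexpected linkage.

    Two signature classes are reported:

    * ``interchromosomal`` -- LOD >= threshold between markers on different
      chromosomes (normal meiosis shows none; the default of 5 keeps the
      expected number of multiple-testing false positives below ~0.1 over
      a 143-marker genome);
    * ``long_range`` -- *tight* linkage (``r_hat <= r_max``) with
      LOD >= threshold between same-chromosome markers at a physical
      distance >= ``dist_threshold_mbp``.  Ordinary chromatids recombine
      freely at such distances (r approaches 0.5); markers flanking an
      inversion stay locked together.
    """
    if lod_threshold <= 0 or dist_threshold_mbp <= 0 or not 0 < r_max <= 0.5:
        raise ValueError("thresholds must be positive (and r_max in (0, 0.5])")
    t = matrix.marker_map.table
    chroms = t["chromosome"].to_numpy()
    pos = t["pos_bp"].to_numpy() / 1e6
    ids = t["marker_id"].to_numpy()
    lod = matrix.lod
    rows = []
    m = len(ids)
    for i in range(m):
        for j in range(i + 1, m):
            score = lod[i, j]
            if not np.isfinite(score) or score < lod_threshold:
                continue
            if chroms[i] != chroms[j]:
                rows.append((ids[i], ids[j], chroms[i], chroms[j], np.nan, score, "interchromosomal"))
            else:
                d = abs(pos[j] - pos[i])
                if d >= dist_threshold_mbp and matrix.r_hat[i, j] <= r_max:
                    rows.append((ids[i], ids[j], chroms[i], chroms[j], d, score, "long_range"))
    return pd.DataFrame(
        rows,
        columns=["marker_a", "marker_b", "chrom_a", "chrom_b", "dist_mbp", "lod", "kind"],
    )


def plot_lod_heatmap(matrix: LODMatrix, path, vmax: float | None = None) -> None:
    """Render the LOD matrix as a heat map image (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(matrix.lod, cmap="viridis", vmax=vmax, interpolation="nearest")
    fig.colorbar(im, ax=ax, label="LOD")
    t = matrix.marker_map.table
    bounds = np.flatnonzero(t["chromosome"].to_numpy()[1:] != t["chromosome"].to_numpy()[:-1]) + 0.5
    for b in bounds:
        ax.axhline(b, color="w", lw=0.5)
        ax.axvline(b, color="w", lw=0.5)
    ax.set_xlabel("marker index")
    ax.set_ylabel("marker index")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
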