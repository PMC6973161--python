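"""Crossover landscapes: CO counting, genetic maps, Marey rates, distortion.

Crossovers are scored as allele changes between consecutive informative
(non-missing) calls along a chromosome.  A switch whose flanking informative
markers are separated by missing calls is assigned to the spanned
super-interval and recorded at its leftmost elementary interval; one such
switch counts as a single CO (minimum-recombination convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from invcross.io import HET, MISSING, GenotypeMatrix, MarkerMap

#: recombination fractions are clamped below this before the Kosambi transform
R_CAP = 0.4999


@dataclass
class COProfile:
    """Per-individual, per-chromosome crossover calls.

    ``counts`` is a DataFrame (individuals x chromosomes) of CO counts; a
    chromosome with fewer than two informative calls for an individual is
    recorded as NaN (undefined), not zero.  ``intervals`` maps
    ``(individual, chromosome)`` to the list of within-chromosome interval
    indices (0-based, leftmost of the spanned run) where switches occurred.
    """

    counts: pd.DataFrame
    intervals: dict[tuple[str, str], list[int]] = field(default_factory=dict, repr=False)

    def total(self, chromosome: str | None = None) -> float:
        if chromosome is None:
            return float(np.nansum(self.counts.to_numpy()))
        return float(self.counts[chromosome].sum(skipna=True))


def count_crossovers(genotypes: GenotypeMatrix) -> COProfile:
    """Score allele changes across single chromosomes for every individual."""
    mm = genotypes.marker_map
    counts = pd.DataFrame(
        index=pd.Index(genotypes.individuals, name="individual"),
        columns=pd.Index(mm.chromosomes, name="chromosome"),
        dtype=float,
    )
    intervals: dict[tuple[str, str], list[int]] = {}
    for chrom in mm.chromosomes:
        calls = genotypes.chromosome_calls(chrom)
        for i, ind in enumerate(genotypes.individuals):
            row = calls[i]
            informative = np.flatnonzero(row != MISSING)
            if informative.size < 2:
                continue
            vals = row[informative]
            switch = np.flatnonzero(vals[1:] != vals[:-1])
            counts.loc[ind, chrom] = float(switch.size)
            if switch.size:
                intervals[(ind, chrom)] = [int(informative[s]) for s in switch]
    return COProfile(counts=counts, intervals=intervals)


def per_cell_mean(total_cos: float, n_individuals: int) -> float:
    """Mean CO number per meiotic cell: ``2 * total / n``.

    Each BC1 plant reveals one gamete, which carries on average half the
    chiasmata of the bivalent; doubling the per-gamete mean therefore gives
    the per-cell mean.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    return 2.0 * total_cos / n_individuals


def kosambi_cm(r: float | np.ndarray) -> float | np.ndarray:
    """Kosambi map distance d = 25 ln((1+2r)/(1-2r)) in centimorgans."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Inverse Kosambi function: r = tanh(d/50) / 2."""
    d = np.asarray(d_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


@dataclass
class GeneticMap:
    """Adjacent-interval recombination fractions and Kosambi distances.

    ``intervals`` has one row per adjacent marker pair with columns
    ``chromosome, left, right, recombinant, informative, r, d_cm``.
    """

    intervals: pd.DataFrame

    def total_cm(self, chromosome: str | None = None) -> float:
        t = self.intervals
        if chromosome is not None:
            t = t[t["chromosome"] == chromosome]
        return float(t["d_cm"].sum(skipna=True))

    def chromosome_table(self, chromosome: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chromosome"] == chromosome].reset_index(drop=True)


def build_genetic_map(genotypes: GenotypeMatrix) -> GeneticMap:
    """Estimate r per adjacent-marker interval and convert via Kosambi.

    r-hat is the recombinant fraction among individuals called at both
    flanking markers.  Intervals with no informative individual get r = NaN
    and zero length.  Marker order is taken from the marker map (reference
    order); no re-ordering is attempted.
    """
    mm = genotypes.marker_map
    rows = []
    ids = mm.marker_ids
    for chrom in mm.chromosomes:
        sl = mm.chromosome_slice(chrom)
        calls = genotypes.calls[:, sl]
        left_ids = ids[sl][:-1]
        right_ids = ids[sl][1:]
        a, b = calls[:, :-1], calls[:, 1:]
        valid = (a != MISSING) & (b != MISSING)
        rec = valid & (a != b)
        n_inf = valid.sum(axis=0)
        n_rec = rec.sum(axis=0)
        with np.errstate(invalid="ignore"):
            r = np.where(n_inf > 0, n_rec / np.maximum(n_inf, 1), np.nan)
        r_clamped = np.minimum(r, R_CAP)
        d = np.where(np.isnan(r), 0.0, 25.0 * np.log((1 + 2 * r_clamped) / (1 - 2 * r_clamped)))
        for k in range(len(left_ids)):
            rows.append(
                (chrom, left_ids[k], right_ids[k], int(n_rec[k]), int(n_inf[k]),
                 float(r[k]) if n_inf[k] else np.nan, float(d[k]))
            )
    table = pd.DataFrame(
        rows, columns=["chromosome", "left", "right", "recombinant", "informative", "r", "d_cm"]
    )
    return GeneticMap(table)


@dataclass
class MareyTrack:
    """Cumulative genetic position against physical position, per chromosome.

    ``points`` columns: ``chromosome, marker_id, pos_mbp, cum_cm``;
    ``rates`` columns: ``chromosome, left, right, mbp_span, d_cm, rate_cm_per_mbp``.
    """

    points: pd.DataFrame
    rates: pd.DataFrame

    def chromosome_rate(self, chromosome: str) -> float:
        """Chromosome-wide rate: total cM over marker span in Mbp."""
        pts = self.points[self.points["chromosome"] == chromosome]
        span = pts["pos_mbp"].iloc[-1] - pts["pos_mbp"].iloc[0]
        if span <= 0:
            raise ValueError(f"zero physical span on chromosome {chromosome}")
        return float(pts["cum_cm"].iloc[-1] / span)


def marey_recombination_rates(genetic_map: GeneticMap, marker_map: MarkerMap) -> MareyTrack:
    """Piecewise recombination rates (cM/Mbp) from the Marey curve slope."""
    points, rates = [], []
    for chrom in marker_map.chromosomes:
        sl = marker_map.chromosome_slice(chrom)
        ids = marker_map.marker_ids[sl]
        mbp = marker_map.positions_mbp(chrom)
        sub = genetic_map.chromosome_table(chrom)
        d = sub["d_cm"].to_numpy()
        cum = np.concatenate([[0.0], np.cumsum(d)])
        for mid, x, c in zip(ids, mbp, cum):
            points.append((chrom, mid, float(x), float(c)))
        spans = np.diff(mbp)
        if np.any(spans <= 0):
            raise ValueError(f"zero physical span between adjacent markers on chromosome {chrom}")
        for k in range(len(spans)):
            rates.append(
                (chrom, ids[k], ids[k + 1], float(spans[k]), float(d[k]), float(d[k] / spans[k]))
            )
    return MareyTrack(
        points=pd.DataFrame(points, columns=["chromosome", "marker_id", "pos_mbp", "cum_cm"]),
        rates=pd.DataFrame(
            rates, columns=["chromosome", "left", "right", "mbp_span", "d_cm", "rate_cm_per_mbp"]
        ),
    )


@dataclass
class DistortionScan:
    """Per-marker segregation check against the 1:1 BC1 expectation.

    A marker is flagged when the heterozygote frequency deviates from 0.5 by
    more than ``k_sd`` binomial standard deviations ``sqrt(0.25 / n)``.
    """

    table: pd.DataFrame
    k_sd: float

    @property
    def flagged(self) -> list[str]:
        t = self.table
        return t.loc[t["flagged"].fillna(False), "marker_id"].tolist()


def segregation_distortion_scan(genotypes: GenotypeMatrix, k_sd: float = 2.0) -> DistortionScan:
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    calls = genotypes.calls
    informative = calls != MISSING
    n = informative.sum(axis=0)
    het = (calls == HET).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n > 0, het / np.maximum(n, 1), np.nan)
        delta = np.where(n > 0, np.sqrt(0.25 / np.maximum(n, 1)), np.nan)
    flagged = np.abs(freq - 0.5) > k_sd * delta
    table = genotypes.marker_map.table[["marker_id", "chromosome", "pos_bp"]].copy()
    table["n_informative"] = n
    table["freq_het"] = freq
    table["delta"] = delta
    table["flagged"] = pd.array(np.where(n > 0, flagged, None), dtype="boolean")
    return DistortionScan(table=table, k_sd=k_sd)


def compare_co_distributions(
    counts_a: np.ndarray | list[int], counts_b: np.ndarray | list[int]
) -> tuple[float, float]:
    """Contingency chi-square for two CO-count histograms with shared bins.

    Bins empty in both histograms are dropped.  Returns ``(chi2, p)``.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("histograms must share bin structure")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("fewer than 2 usable bins")
    if np.array_equal(a, b):
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(np.vstack([a, b]), correction=False)
    return float(chi2), float(p)


def co_count_histogram(profile: COProfile, chromosome: str, max_count: int | None = None) -> np.ndarray:
    """Histogram of per-individual CO counts for one chromosome."""
    c = profile.counts[chromosome].dropna().astype(int).to_numpy()
    top = int(c.max()) if max_count is None and c.size else (max_count or 0)
    return np.bincount(c, minlength=top + 1)
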