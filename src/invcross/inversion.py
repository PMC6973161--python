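"""Pairing + post-meiotic-selection model for a pericentric-inversion heterozygote.

Model
-----
In a heterozygote for a large pericentric inversion, homologs pair in exactly
one of three regions per meiosis: the short arm outside the inversion
(region 1), the inverted segment itself (region 2) or the long arm outside
the inversion (region 3), with probabilities ``(P1, P2, P3)`` summing to one.
Conditional on pairing, the gamete's crossover count in the paired region is
Poisson with mean ``lambda_i`` (no interference -- the assumption that makes
the pre/post-selection rate relation closed-form).  Gametes with an odd
number of COs inside the inversion carry duplications/deficiencies and are
eliminated post-meiotically; only even counts survive.

For ``N ~ Poisson(lam)`` the selection algebra is::

    P(N even)            = (1 + exp(-2 lam)) / 2
    P(N even and N >= 2) = (1 + exp(-2 lam)) / 2 - exp(-lam)
    E[N ; N even]        = lam (1 - exp(-2 lam)) / 2

and the viable fraction of all gametes is ``Z = 1 - P2 (1 - exp(-2 lam2))/2``.

Calibration
-----------
The pairing probabilities are unobservable (they act before selection) and
are calibrated from the observable region-event classes of a BC1 population:
individuals whose chromosome-3 COs fall exclusively in region 1, exclusively
in the inversion (even counts only), exclusively in region 3, or nowhere
(pairing region unknown).  Per candidate ``(P1, P2)`` the intensities are
profiled out by requiring the model to replicate the observed post-selection
mean CO count of each region; the candidate is then scored by the agreement
between expected and observed class frequencies.  Because the zero-CO class
carries no pairing information of its own, the default score matches the
three pairing shares among CO-carrying individuals plus the zero-CO
probability (least squares).  The surface is shallow in places -- the fit
report exposes the full grid so the flat directions can be inspected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

from invcross.io import HET, REC, GenotypeMatrix, MarkerMap
from invcross.landscape import COProfile
from invcross.linkage import LODMatrix, lod_heatmap

logger = logging.getLogger(__name__)

REGION_NAMES = ("region1", "inversion", "region3")


def gamete_viable(co_count_in_inversion: int) -> bool:
    """A gamete is viable iff its inversion CO count is even (0 included)."""
    if co_count_in_inversion < 0:
        raise ValueError("CO count must be non-negative")
    return co_count_in_inversion % 2 == 0


def even_conditioned_moments(lam: float) -> tuple[float, float, float]:
    """Closed-form moments of ``N ~ Poisson(lam)`` under the even-count rule.

    Returns ``(P(N even), P(N even and N >= 2), E[N ; N even])``.
    """
    if lam < 0:
        raise ValueError("intensity must be non-negative")
    p_even = (1.0 + math.exp(-2.0 * lam)) / 2.0
    p_even_ge2 = p_even - math.exp(-lam)
    mean_even = lam * (1.0 - math.exp(-2.0 * lam)) / 2.0
    return p_even, p_even_ge2, mean_even


@dataclass(frozen=True)
class RegionPartition:
    """Marker-interval layout of the rearranged chromosome.

    Marker indices are 0-based within the chromosome.  The two breakpoint
    intervals (between region 1 and the inversion, and between the inversion
    and region 3) belong to no region: their COs are tallied separately and
    excluded from calibration.
    """

    chromosome: str
    region1: tuple[int, int]
    inversion: tuple[int, int]
    region3: tuple[int, int]
    n_markers: int

    @classmethod
    def from_markers(
        cls,
        marker_map: MarkerMap,
        chromosome: str,
        region1: tuple[str, str],
        inversion: tuple[str, str],
        region3: tuple[str, str],
    ) -> "RegionPartition":
        sl = marker_map.chromosome_slice(chromosome)
        ids = marker_map.marker_ids[sl]
        index = {m: k for k, m in enumerate(ids)}

        def rng(pair: tuple[str, str]) -> tuple[int, int]:
            a, b = index[pair[0]], index[pair[1]]
            if a > b:
                raise ValueError(f"region markers out of order: {pair}")
            return a, b

        part = cls(
            chromosome=chromosome,
            region1=rng(region1),
            inversion=rng(inversion),
            region3=rng(region3),
            n_markers=len(ids),
        )
        part.validate()
        return part

    def validate(self) -> None:
        r1, inv, r3 = self.region1, self.inversion, self.region3
        if not (r1[0] == 0 and r1[1] + 1 == inv[0] and inv[1] + 1 == r3[0] and r3[1] == self.n_markers - 1):
            raise ValueError(
                "regions must be ordered, disjoint and jointly cover the chromosome "
                f"(got {r1}, {inv}, {r3} over {self.n_markers} markers)"
            )

    def region_intervals(self, name: str) -> range:
        """Within-region marker-interval indices (interval j = markers j, j+1)."""
        lo, hi = getattr(self, name)
        return range(lo, hi)

    @property
    def spanning_intervals(self) -> tuple[int, int]:
        """The two breakpoint-spanning interval indices."""
        return self.region1[1], self.inversion[1]

    def interval_region(self, interval: int) -> str:
        """Region name for an interval index, or ``"spanning"``."""
        if interval in self.spanning_intervals:
            return "spanning"
        for name in REGION_NAMES:
            lo, hi = getattr(self, name)
            if lo <= interval < hi:
                return name
        raise ValueError(f"interval {interval} outside chromosome")


@dataclass(frozen=True)
class PairingModel:
    """Pairing probabilities and pre-selection CO intensities per region."""

    p1: float
    p2: float
    p3: float
    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        probs = (self.p1, self.p2, self.p3)
        if min(probs) < -1e-12 or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("pairing probabilities must be a simplex")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def probabilities(self) -> tuple[float, float, float]:
        return self.p1, self.p2, self.p3

    @property
    def intensities(self) -> tuple[float, float, float]:
        return self.lambda1, self.lambda2, self.lambda3

    @property
    def viability(self) -> float:
        """Z: probability that a random gamete survives selection."""
        return 1.0 - self.p2 * (1.0 - math.exp(-2.0 * self.lambda2)) / 2.0

    def class_probabilities(self, interval_counts: tuple[int, int, int] | None = None) -> dict[str, float]:
        """Post-selection probabilities of the observable event classes.

        With ``interval_counts`` the classes are what marker data can show:
        a region is "hit" when at least one of its intervals holds an odd CO
        count (COs spread uniformly over the region's intervals), and the
        inversion class requires an even number of switched intervals.
        Without it the classes are the idealised full-resolution ones
        (any CO detected).
        """
        z = self.viability
        if interval_counts is None:
            _, p_ge2_even, _ = even_conditioned_moments(self.lambda2)
            c1 = self.p1 * (1.0 - math.exp(-self.lambda1)) / z
            c2 = self.p2 * p_ge2_even / z
            c3 = self.p3 * (1.0 - math.exp(-self.lambda3)) / z
        else:
            k1, k2, k3 = interval_counts
            q1 = _interval_odd_prob(self.lambda1, k1)
            q2 = _interval_odd_prob(self.lambda2, k2)
            q3 = _interval_odd_prob(self.lambda3, k3)
            t = 1.0 - 2.0 * q2
            c1 = self.p1 * (1.0 - (1.0 - q1) ** k1) / z
            c2 = self.p2 * ((1.0 + t**k2) / 2.0 - (1.0 - q2) ** k2) / z
            c3 = self.p3 * (1.0 - (1.0 - q3) ** k3) / z
        return {"region1": c1, "inversion": c2, "region3": c3, "zero": 1.0 - c1 - c2 - c3}


@dataclass
class RegionEventTable:
    """Observable chromosome-3 event classes of one BC1 population.

    ``class_counts`` holds the mutually exclusive classes ``region1``,
    ``inversion``, ``region3``, ``zero`` plus ``spanning`` (COs only in a
    breakpoint interval) and ``mixed`` (COs in more than one region --
    exclusivity violations).  ``mean_counts`` are the observed mean CO counts
    per gamete attributable to each region, the quantities the calibration
    replicates.
    """

    n: int
    class_counts: dict[str, int]
    mean_counts: tuple[float, float, float]
    interval_counts: tuple[int, int, int] = (1, 20, 3)
    histograms: dict[str, dict[int, int]] = field(default_factory=dict)
    mixed_individuals: list[str] = field(default_factory=list)

    @classmethod
    def from_class_counts(
        cls,
        n: int,
        region1: dict[int, int] | int,
        inversion: dict[int, int] | int,
        region3: dict[int, int] | int,
        interval_counts: tuple[int, int, int] = (1, 20, 3),
    ) -> "RegionEventTable":
        """Build from printed per-region CO-count tallies.

        Each region accepts either ``{co_count: n_individuals}`` or a plain
        count of single-CO individuals.  The zero class is the remainder.
        """

        def as_hist(x) -> dict[int, int]:
            return {1: int(x)} if isinstance(x, (int, np.integer)) else {int(k): int(v) for k, v in x.items() if k > 0}

        hists = {"region1": as_hist(region1), "inversion": as_hist(inversion), "region3": as_hist(region3)}
        counts = {name: sum(h.values()) for name, h in hists.items()}
        zero = n - sum(counts.values())
        if zero < 0:
            raise ValueError("class counts exceed population size")
        means = tuple(
            sum(k * v for k, v in hists[name].items()) / n for name in REGION_NAMES
        )
        return cls(
            n=n,
            class_counts={**counts, "zero": zero, "spanning": 0, "mixed": 0},
            mean_counts=means,  # type: ignore[arg-type]
            interval_counts=interval_counts,
            histograms=hists,
        )

    @property
    def class_vector(self) -> np.ndarray:
        """Counts of (region1, inversion, region3, zero)."""
        c = self.class_counts
        return np.array([c["region1"], c["inversion"], c["region3"], c["zero"]], dtype=float)


def classify_region_events(
    profiles: COProfile, partition: RegionPartition
) -> RegionEventTable:
    """Assign every individual to one observable region-event class.

    COs in the two breakpoint-spanning intervals do not contribute to any
    region; an individual whose only COs are spanning falls in the
    ``spanning`` class, and the ``zero`` class means no CO anywhere on the
    chromosome.  Individuals with COs in two or more regions are ``mixed``.
    """
    chrom = partition.chromosome
    counts = {k: 0 for k in ("region1", "inversion", "region3", "zero", "spanning", "mixed")}
    hists: dict[str, dict[int, int]] = {name: {} for name in REGION_NAMES}
    totals = dict.fromkeys(REGION_NAMES, 0)
    mixed: list[str] = []
    sl_offset = 0  # profile interval indices are already within-chromosome
    n = 0
    for ind in profiles.counts.index:
        if np.isnan(profiles.counts.loc[ind, chrom]):
            continue
        n += 1
        intervals = profiles.intervals.get((ind, chrom), [])
        per_region = dict.fromkeys(REGION_NAMES, 0)
        spanning = 0
        for iv in intervals:
            where = partition.interval_region(iv - sl_offset)
            if where == "spanning":
                spanning += 1
            else:
                per_region[where] += 1
        for name in REGION_NAMES:
            totals[name] += per_region[name]
        active = [name for name in REGION_NAMES if per_region[name] > 0]
        if len(active) > 1:
            counts["mixed"] += 1
            mixed.append(str(ind))
        elif len(active) == 1:
            name = active[0]
            counts[name] += 1
            hists[name][per_region[name]] = hists[name].get(per_region[name], 0) + 1
        elif spanning > 0:
            counts["spanning"] += 1
        else:
            counts["zero"] += 1
    if n == 0:
        raise ValueError("no individual has a defined CO count on the partition chromosome")
    means = tuple(totals[name] / n for name in REGION_NAMES)
    ks = tuple(len(partition.region_intervals(name)) for name in REGION_NAMES)
    return RegionEventTable(
        n=n,
        class_counts=counts,
        mean_counts=means,
        interval_counts=ks,  # type: ignore[arg-type]
        histograms=hists,
        mixed_individuals=mixed,
    )


# ---------------------------------------------------------------------------
# calibration


def _interval_odd_prob(lam_total: float, k: int) -> float:
    """P(odd Poisson count) in one of ``k`` intervals sharing intensity ``lam_total``."""
    return (1.0 - math.exp(-2.0 * lam_total / k)) / 2.0


def _profile_lambda2(p2: float, s2: float, k2: int) -> float | None:
    """Pre-selection inversion intensity replicating the observed switch rate.

    ``s2`` is the observed mean number of switched inversion intervals per
    gamete.  A switch in interval ``j`` is observable only on viable gametes,
    which requires an odd CO count among the other ``k2 - 1`` intervals, so
    with per-interval odd-probability ``q`` (``t = 1 - 2q``)::

        P2 * k2 * q * (1 - t**(k2-1)) / 2 = s2 * Z,   Z = 1 - P2 (1 - t**k2)/2

    Returns the total intensity ``lambda2 = -k2 ln(t) / 2`` or None when no
    feasible root exists.
    """
    if s2 <= 0:
        return 0.0
    if p2 <= 0:
        return None

    def f(q: float) -> float:
        t = 1.0 - 2.0 * q
        z = 1.0 - p2 * (1.0 - t**k2) / 2.0
        return p2 * k2 * q * (1.0 - t ** (k2 - 1)) / 2.0 - s2 * z

    hi = 0.5 - 1e-12
    if f(hi) < 0:
        return None
    q = brentq(f, 0.0, hi, xtol=1e-15)
    return -k2 * math.log(1.0 - 2.0 * q) / 2.0


def _profiled_model(
    p1: float,
    p2: float,
    means: tuple[float, float, float],
    interval_counts: tuple[int, int, int],
) -> PairingModel | None:
    """PairingModel at ``(p1, p2)`` replicating the observed switch rates.

    ``means`` are observed mean switch counts per gamete per region; the
    per-region intensities are the unique pre-selection values for which the
    model's post-selection switch rates equal them.
    """
    p3 = 1.0 - p1 - p2
    if min(p1, p2, p3) < 0:
        return None
    s1, s2, s3 = means
    k1, k2, k3 = interval_counts
    lam2 = _profile_lambda2(p2, s2, k2)
    if lam2 is None:
        return None
    z = 1.0 - p2 * (1.0 - math.exp(-2.0 * lam2)) / 2.0

    def outer(p: float, s: float, k: int) -> float | None:
        if p <= 0:
            return 0.0 if s <= 0 else None
        q = s * z / (p * k)
        if q >= 0.5:
            return None
        return -k * math.log(1.0 - 2.0 * q) / 2.0

    lam1 = outer(p1, s1, k1)
    lam3 = outer(p3, s3, k3)
    if lam1 is None or lam3 is None:
        return None
    return PairingModel(p1, p2, p3, lam1, lam2, lam3)


def _score(model: PairingModel, events: RegionEventTable, objective: str) -> float:
    counts = events.class_vector
    n = counts.sum()
    freqs = counts / n
    probs = model.class_probabilities(events.interval_counts)
    p = np.array([probs[k] for k in ("region1", "inversion", "region3", "zero")])
    if np.any(p <= 0) or np.any(p >= 1):
        return np.inf
    if objective == "shares":
        positive = counts[:3].sum()
        if positive <= 0:
            raise ValueError("no CO-carrying individuals: pairing shares undefined")
        obs_shares = counts[:3] / positive
        model_shares = p[:3] / p[:3].sum()
        return float(((model_shares - obs_shares) ** 2).sum() + (p[3] - freqs[3]) ** 2)
    if objective == "multinomial":
        return float(-(counts * np.log(p)).sum())
    if objective == "frequencies":
        return float(((p - freqs) ** 2).sum())
    raise ValueError(f"unknown objective {objective!r}")


@dataclass
class PairingFit:
    """Result of :func:`calibrate_pairing`."""

    model: PairingModel
    objective: str
    objective_value: float
    rounded: tuple[float, float, float]
    grid: pd.DataFrame
    events: RegionEventTable

    def summary(self) -> dict:
        return {
            "pairing_probabilities": dict(zip(("P1", "P2", "P3"), self.rounded)),
            "pairing_probabilities_full": dict(zip(("P1", "P2", "P3"), self.model.probabilities)),
            "intensities_morgans": dict(zip(("lambda1", "lambda2", "lambda3"), self.model.intensities)),
            "viable_fraction_Z": self.model.viability,
            "objective": self.objective,
            "objective_value": self.objective_value,
        }


def calibrate_pairing(
    events: RegionEventTable,
    objective: str = "shares",
    grid_step: float = 0.01,
    refine: bool = True,
) -> PairingFit:
    """Calibrate pairing probabilities from observed region-event classes.

    A full scan of the ``(P1, P2)`` simplex grid (step ``grid_step``) is
    followed by derivative-free (Nelder-Mead) refinement of the best grid
    point.  Intensities are profiled at every candidate by replicating the
    observed per-region mean CO counts, so only two parameters are free.

    The identifiability caveat matters: with few CO-carrying individuals the
    surface develops flat valleys, and different objectives can move the
    optimum by a few hundredths.  The returned :class:`PairingFit` carries
    the whole grid so the surface can be examined.
    """
    mixed = events.class_counts.get("mixed", 0)
    if mixed > 0.05 * events.n:
        raise ValueError(
            f"{mixed}/{events.n} individuals violate region exclusivity; "
            "the single-region pairing model does not apply"
        )
    means = events.mean_counts
    ks = events.interval_counts
    rows = []
    best: tuple[float, float, float] | None = None
    for p1 in np.arange(0.0, 1.0 + 1e-9, grid_step):
        for p2 in np.arange(0.0, 1.0 - p1 + 1e-9, grid_step):
            model = _profiled_model(p1, p2, means, ks)
            value = np.inf if model is None else _score(model, events, objective)
            rows.append((p1, p2, value))
            if np.isfinite(value) and (best is None or value < best[2]):
                best = (p1, p2, value)
    if best is None:
        raise ValueError("no feasible point on the pairing simplex grid")
    p1, p2, value = best
    if refine:
        def wrapped(x: np.ndarray) -> float:
            model = _profiled_model(x[0], x[1], means, ks)
            return np.inf if model is None else _score(model, events, objective)

        res = minimize(
            wrapped,
            np.array([p1, p2]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-8 * max(abs(value), 1e-8), "maxiter": 4000, "maxfev": 4000},
        )
        if np.isfinite(res.fun) and res.fun <= value:
            p1, p2, value = float(res.x[0]), float(res.x[1]), float(res.fun)
    model = _profiled_model(p1, p2, means, ks)
    assert model is not None
    rounded = tuple(round(p, 2) for p in model.probabilities)
    logger.info(
        "calibrated pairing probabilities %s (objective %s = %.4g)", rounded, objective, value
    )
    return PairingFit(
        model=model,
        objective=objective,
        objective_value=value,
        rounded=rounded,  # type: ignore[arg-type]
        grid=pd.DataFrame(rows, columns=["P1", "P2", "score"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# forward simulation


def simulate_inversion_gametes(
    model: PairingModel,
    n: int,
    partition: RegionPartition,
    marker_map: MarkerMap,
    seed: int | np.random.Generator = 0,
    min_survival: float = 1e-6,
    return_truth: bool = False,
):
    """Draw ``n`` viable gametes for the rearranged chromosome.

    Each meiosis pairs one region, draws a Poisson CO count at that region's
    intensity, places the COs uniformly over the region's marker intervals
    (equal genetic weight per interval) and applies the even-count viability
    rule; inviable gametes are redrawn until ``n`` survive.  The parental
    phase at the chromosome start is Bernoulli(1/2) -- immaterial for every
    statistic, but it makes simulated files look like real ones.

    Returns a :class:`~invcross.io.GenotypeMatrix` over the chromosome's
    markers only (a chromosome-restricted marker map).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    z = model.viability
    if z < min_survival:
        raise RuntimeError(f"survival probability {z:.2e} below {min_survival:.0e}; model degenerate")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sl = marker_map.chromosome_slice(partition.chromosome)
    sub = marker_map.table.iloc[sl].reset_index(drop=True)
    chrom_map = MarkerMap(sub)
    n_markers = partition.n_markers
    if len(chrom_map) != n_markers:
        raise ValueError("partition does not match marker map")
    region_intervals = {name: np.array(list(partition.region_intervals(name)), dtype=int) for name in REGION_NAMES}
    lam = np.array(model.intensities)
    probs = np.array(model.probabilities)

    rows: list[np.ndarray] = []
    truth_region: list[str] = []
    truth_count: list[int] = []
    n_rejected = 0
    while len(rows) < n:
        batch = max(64, int((n - len(rows)) / max(z, 0.5) * 1.2))
        regions = rng.choice(3, size=batch, p=probs)
        n_cos = rng.poisson(lam[regions])
        for region_idx, k in zip(regions, n_cos):
            if len(rows) >= n:
                break
            if region_idx == 1 and k % 2 == 1:
                n_rejected += 1
                continue
            ivs = region_intervals[REGION_NAMES[region_idx]]
            flips = np.zeros(n_markers - 1, dtype=int)
            if k > 0 and ivs.size > 0:
                chosen = rng.choice(ivs, size=int(k), replace=True)
                np.add.at(flips, chosen, 1)
            phase = int(rng.integers(2))
            calls = (phase + np.concatenate([[0], np.cumsum(flips)])) % 2
            rows.append(calls)
            truth_region.append(REGION_NAMES[region_idx])
            truth_count.append(int(k))
    calls = np.array(rows[:n], dtype=np.int8)
    calls = np.where(calls == 1, HET, REC).astype(np.int8)
    individuals = [f"sim{i + 1:05d}" for i in range(n)]
    genotypes = GenotypeMatrix(individuals, calls, chrom_map, population_label="simulated")
    if return_truth:
        truth = {
            "pairing_region": truth_region[:n],
            "n_cos_true": np.array(truth_count[:n]),
            "n_rejected": n_rejected,
        }
        return genotypes, truth
    return genotypes


def predict_lod_heatmap(
    model: PairingModel,
    partition: RegionPartition,
    marker_map: MarkerMap,
    n: int,
    seed: int | np.random.Generator = 0,
) -> LODMatrix:
    """Model-predicted two-point LOD heat map for the rearranged chromosome."""
    simulated = simulate_inversion_gametes(model, n, partition, marker_map, seed=seed)
    return lod_heatmap(simulated)
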