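"""Synthetic four-population BC1 generator with ground-truth logs.

The generator reproduces the statistical structure the analysis assumes:
five chromosomes carrying 143 SNP markers at roughly 0.8 Mb spacing, four
reciprocal backcross populations (control/mutant x male/female), sex-specific
genetic lengths (heterochiasmy), gamma-model interference on structurally
normal chromosomes, an optional pericentric inversion on chromosome 3
simulated through the pairing + post-meiotic-selection model, and an
optional interchromosomal boost of CO rates on the non-rearranged
chromosomes of the mutant.  Genetic positions are taken proportional to
physical positions (flat cM/Mbp); real chromosomes suppress COs around the
centromere, which this default deliberately ignores.

Every gamete's true CO positions are logged next to the marker-visible
switch count, so tests can separate process truth from what genotypes can
show (a double CO inside one marker interval is invisible).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from invcross.interference import GammaParams, simulate_two_pathway
from invcross.inversion import (
    PairingModel,
    RegionPartition,
    _profiled_model,
    simulate_inversion_gametes,
)
from invcross.io import HET, MISSING, REC, GenotypeMatrix, MarkerMap, PopulationSet

#: populations of the reciprocal-backcross design and their sizes
POPULATION_SIZES = {"Mctr": 414, "Mmut": 418, "Fctr": 416, "Fmut": 419}

#: control genetic lengths per gamete (Morgans), from observed per-cell CO means
CONTROL_LENGTHS = {
    "male": {"1": 1.17, "2": 0.67, "3": 0.91, "4": 0.755, "5": 1.015},
    "female": {"1": 0.7877, "2": 0.6212, "3": 0.56, "4": 0.625, "5": 0.6811},
}

#: interchromosomal CO-rate boost on non-rearranged chromosomes of the mutant
IC_BOOST = {
    "male": {"1": 1.13, "2": 1.21, "3": 1.0, "4": 1.0, "5": 1.22},
    "female": {"1": 1.0, "2": 1.0, "3": 1.0, "4": 1.0, "5": 1.0},
}

#: two-pathway gamma interference parameters (shape nu, escape fraction p);
#: interference is markedly stronger in female meiosis
GAMMA = {"male": (3.0, 0.10), "female": (6.0, 0.05)}

#: pairing probabilities of the inversion heterozygote (region1, inversion, region3)
PAIRING_PROBS = {"male": (0.08, 0.17, 0.75), "female": (0.06, 0.19, 0.75)}

#: observed per-region mean CO counts per gamete used to set pre-selection intensities
REGION_MEANS = {
    "male": (3 / 418, 36 / 418, 48 / 418),
    "female": (5 / 419, 8 / 419, 82 / 419),
}

INVERSION_REGIONS = {
    "region1": ("CH3-1", "CH3-2"),
    "inversion": ("CH3-3", "CH3-23"),
    "region3": ("CH3-24", "CH3-27"),
}


def default_marker_map() -> MarkerMap:
    """143 markers over 5 chromosomes, ~0.8 Mb spacing.

    Chromosome 3 carries 27 markers with the breakpoint-flanking anchors at
    their true physical coordinates; other chromosomes are evenly spaced.
    """
    sizes_mbp = {"1": 30.4, "2": 19.7, "4": 18.6, "5": 27.0}
    counts = {"1": 36, "2": 24, "4": 23, "5": 33}
    records: list[tuple[str, str, int]] = []
    for chrom in ("1", "2"):
        records += _even_markers(chrom, counts[chrom], sizes_mbp[chrom])
    records += _chromosome3_markers()
    for chrom in ("4", "5"):
        records += _even_markers(chrom, counts[chrom], sizes_mbp[chrom])
    return MarkerMap.from_records(records)


def _even_markers(chrom: str, k: int, size_mbp: float) -> list[tuple[str, str, int]]:
    pos = np.linspace(0.3e6, size_mbp * 1e6 - 0.3e6, k).astype(int)
    return [(f"C{chrom}-{i + 1}", chrom, int(p)) for i, p in enumerate(pos)]


def _chromosome3_markers() -> list[tuple[str, str, int]]:
    anchors = {1: 120_000, 2: 597_345, 3: 1_484_401, 23: 20_283_184, 24: 21_164_570, 27: 23_300_000}
    pos = {**anchors}
    inner = np.linspace(anchors[3], anchors[23], 21).astype(int)  # CH3-3 .. CH3-23
    for k, p in zip(range(3, 24), inner):
        pos[k] = int(p)
    tail = np.linspace(anchors[24], anchors[27], 4).astype(int)  # CH3-24 .. CH3-27
    for k, p in zip(range(24, 28), tail):
        pos[k] = int(p)
    return [(f"CH3-{k}", "3", pos[k]) for k in range(1, 28)]


def inversion_partition(marker_map: MarkerMap) -> RegionPartition:
    return RegionPartition.from_markers(
        marker_map,
        chromosome="3",
        region1=INVERSION_REGIONS["region1"],
        inversion=INVERSION_REGIONS["inversion"],
        region3=INVERSION_REGIONS["region3"],
    )


def pairing_model(sex: str) -> PairingModel:
    """Inversion pairing model with intensities profiled from observed means."""
    p1, p2, _ = PAIRING_PROBS[sex]
    model = _profiled_model(p1, p2, REGION_MEANS[sex], (1, 20, 3))
    assert model is not None
    return model


@dataclass
class SimScenario:
    """Full generative description of one synthetic BC1 population."""

    label: str
    n_individuals: int
    sex: str
    mutant: bool
    marker_map: MarkerMap
    lengths_morgans: dict[str, float]
    gamma_nu: float
    gamma_p: float
    boosts: dict[str, float]
    inversion: PairingModel | None
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if any(v < 0 for v in self.lengths_morgans.values()):
            raise ValueError("genetic lengths must be non-negative")
        if any(b <= 0 for b in self.boosts.values()):
            raise ValueError("boosts must be positive")
        if self.inversion is not None and "3" not in self.marker_map.chromosomes:
            raise ValueError("inversion set but chromosome 3 absent from map")


def preset(name: str, n: int | None = None, seed: int = 0, missing_rate: float = 0.02) -> SimScenario:
    """Named scenario: control_male, mutant_male, control_female, mutant_female."""
    table = {
        "control_male": ("Mctr", "male", False),
        "mutant_male": ("Mmut", "male", True),
        "control_female": ("Fctr", "female", False),
        "mutant_female": ("Fmut", "female", True),
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; options: {sorted(table)}")
    label, sex, mutant = table[name]
    mm = default_marker_map()
    return SimScenario(
        label=label,
        n_individuals=n if n is not None else POPULATION_SIZES[label],
        sex=sex,
        mutant=mutant,
        marker_map=mm,
        lengths_morgans=dict(CONTROL_LENGTHS[sex]),
        gamma_nu=GAMMA[sex][0],
        gamma_p=GAMMA[sex][1],
        boosts=dict(IC_BOOST[sex]) if mutant else {c: 1.0 for c in "12345"},
        inversion=pairing_model(sex) if mutant else None,
        missing_rate=missing_rate,
        seed=seed,
    )


def generate_bc1(scenario: SimScenario) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate one BC1 population and its ground-truth log.

    The truth log has one row per (individual, chromosome) with the true CO
    count, the marker-visible switch count, and -- for the rearranged
    chromosome -- the paired region.
    """
    rng = np.random.default_rng(scenario.seed)
    mm = scenario.marker_map
    n = scenario.n_individuals
    individuals = [f"{scenario.label}-{i + 1:04d}" for i in range(n)]
    calls = np.empty((n, len(mm)), dtype=np.int8)
    truth_rows: list[tuple] = []

    for chrom in mm.chromosomes:
        sl = mm.chromosome_slice(chrom)
        k = sl.stop - sl.start
        if scenario.mutant and scenario.inversion is not None and chrom == "3":
            part = inversion_partition(mm)
            sim, truth = _inversion_with_truth(scenario.inversion, n, part, mm, rng)
            calls[:, sl] = sim.calls
            visible = _switch_counts(sim.calls)
            for i, ind in enumerate(individuals):
                truth_rows.append((scenario.label, ind, chrom, truth["n_cos"][i], int(visible[i]), truth["region"][i]))
            continue
        length = scenario.lengths_morgans[chrom] * scenario.boosts.get(chrom, 1.0)
        if length == 0:
            positions: list[np.ndarray] = [np.empty(0)] * n
        else:
            params = GammaParams(nu=scenario.gamma_nu, p=scenario.gamma_p, map_length_morgans=length)
            positions = simulate_two_pathway(params, n, rng)
        pos_bp = mm.table["pos_bp"].to_numpy()[sl].astype(float)
        boundaries = length * (pos_bp - pos_bp[0]) / (pos_bp[-1] - pos_bp[0]) if length else np.zeros(k)
        for i, ind in enumerate(individuals):
            flips = np.zeros(k - 1, dtype=int)
            if positions[i].size:
                iv = np.searchsorted(boundaries, positions[i], side="right") - 1
                iv = np.clip(iv, 0, k - 2)
                np.add.at(flips, iv, 1)
            phase = int(rng.integers(2))
            row = (phase + np.concatenate([[0], np.cumsum(flips)])) % 2
            calls[i, sl] = np.where(row == 1, HET, REC)
            visible = int((flips % 2).sum())
            truth_rows.append((scenario.label, ind, chrom, int(positions[i].size), visible, ""))

    if scenario.missing_rate > 0:
        mask = rng.random(calls.shape) < scenario.missing_rate
        # never blank out an entire individual
        for i in np.flatnonzero(mask.all(axis=1)):
            mask[i, rng.integers(calls.shape[1])] = False
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    genotypes = GenotypeMatrix(individuals, calls, mm, population_label=scenario.label)
    truth = pd.DataFrame(
        truth_rows,
        columns=["population", "individual", "chromosome", "n_cos_true", "n_cos_visible", "pairing_region"],
    )
    return genotypes, truth


def _switch_counts(calls: np.ndarray) -> np.ndarray:
    return (calls[:, 1:] != calls[:, :-1]).sum(axis=1)


def _inversion_with_truth(
    model: PairingModel, n: int, part: RegionPartition, mm: MarkerMap, rng: np.random.Generator
):
    """simulate_inversion_gametes plus per-gamete truth (region, true CO count)."""
    sim, truth = simulate_inversion_gametes(model, n, part, mm, seed=_child(rng), return_truth=True)
    return sim, {"n_cos": [int(c) for c in truth["n_cos_true"]], "region": truth["pairing_region"]}


def _child(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(rng.integers(2**31))


def generate_population_set(
    names: tuple[str, ...] = ("control_male", "mutant_male", "control_female", "mutant_female"),
    seed: int = 0,
    n: int | None = None,
    missing_rate: float = 0.02,
) -> tuple[PopulationSet, pd.DataFrame]:
    """Generate the full reciprocal-backcross study (shared marker map)."""
    mm = default_marker_map()
    pops: dict[str, GenotypeMatrix] = {}
    logs = []
    for offset, name in enumerate(names):
        scenario = preset(name, n=n, seed=seed + offset, missing_rate=missing_rate)
        scenario = replace(scenario, marker_map=mm)
        g, truth = generate_bc1(scenario)
        pops[scenario.label] = g
        logs.append(truth)
    return PopulationSet(pops), pd.concat(logs, ignore_index=True)
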