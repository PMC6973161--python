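"""Simulate a control backcross population and chart its crossover landscape.

Generates a male control BC1 population (414 plants, 143 SNP markers), counts
crossovers per plant and chromosome, and builds the Kosambi genetic map and
Marey-map recombination rates.
"""

from invcross import build_genetic_map, count_crossovers, marey_recombination_rates, per_cell_mean
from invcross.simulate import generate_bc1, preset

scenario = preset("control_male", seed=1)
genotypes, truth = generate_bc1(scenario)

profile = count_crossovers(genotypes)
total = profile.total()
print(f"population {genotypes.population_label}: {genotypes.n_individuals} plants, "
      f"{int(total)} crossovers")
print(f"per-cell mean CO number: {per_cell_mean(total, genotypes.n_individuals):.2f} "
      "(twice the per-gamete mean; ~9.1 expected for male meiosis)")

gm = build_genetic_map(genotypes)
track = marey_recombination_rates(gm, genotypes.marker_map)
print("\nchromosome  map (cM)  rate (cM/Mbp)")
for chrom in genotypes.marker_map.chromosomes:
    print(f"{chrom:>10}  {gm.total_cm(chrom):8.2f}  {track.chromosome_rate(chrom):13.2f}")
print("\nMap lengths track the simulated genetic lengths; the rate column is "
      "the Marey-curve slope averaged over each chromosome.")
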