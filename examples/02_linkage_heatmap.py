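"""Genome-wide two-point LOD heat maps: control vs inversion heterozygote.

The control shows LOD decaying away from the diagonal and nothing between
chromosomes; the mutant's chromosome 3 keeps distant markers tightly linked
because crossovers inside the heterozygous inversion are suppressed by
post-meiotic selection.
"""

from invcross import flag_anomalous_linkage, lod_heatmap
from invcross.simulate import generate_bc1, preset

for name in ("control_male", "mutant_male"):
    genotypes, _ = generate_bc1(preset(name, n=400, seed=2))
    matrix = lod_heatmap(genotypes)
    flags = flag_anomalous_linkage(matrix)
    ids = matrix.marker_map.marker_ids
    i, j = ids.index("CH3-3"), ids.index("CH3-23")
    print(f"{genotypes.population_label}: LOD(CH3-3, CH3-23) = {matrix.lod[i, j]:6.1f}  "
          f"r-hat = {matrix.r_hat[i, j]:.3f}  long-range flags: "
          f"{(flags['kind'] == 'long_range').sum()}  interchromosomal flags: "
          f"{(flags['kind'] == 'interchromosomal').sum()}")

print("\nThe two markers flank the inverted segment (~19 Mbp apart). In the "
      "control they recombine freely (r-hat near 0.5, LOD ~ 0); in the mutant "
      "they are locked together — the heat-map block signature of an inversion.")
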