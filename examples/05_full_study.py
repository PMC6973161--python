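"""Generate the full four-population reciprocal backcross study and summarise it.

Reproduces the study design end to end on synthetic data: four BC1
populations (control/mutant x male/female) on one 143-marker map, with the
mutant carrying the chromosome-3 pericentric inversion and (in males) an
interchromosomal boost on chromosomes 1, 2 and 5.
"""

from invcross import classify_region_events, count_crossovers, per_cell_mean
from invcross.simulate import generate_population_set, inversion_partition

pops, truth = generate_population_set(seed=4)
part = inversion_partition(pops["Mctr"].marker_map)

print("population  n     total COs  per-cell  chr3 per-cell")
for label in ("Mctr", "Mmut", "Fctr", "Fmut"):
    g = pops[label]
    profile = count_crossovers(g)
    print(f"{label:>10}  {g.n_individuals}   {int(profile.total()):9d}  "
          f"{per_cell_mean(profile.total(), g.n_individuals):8.2f}  "
          f"{per_cell_mean(profile.total('3'), g.n_individuals):13.2f}")

events = classify_region_events(count_crossovers(pops["Mmut"]), part)
print("\nMmut chromosome-3 region classes:", {
    k: v for k, v in events.class_counts.items() if v
})
print("\nThe mutants lose chromosome-3 COs to the inversion (per-cell ~0.5 vs "
      "~1.8 in the male control) while the male interchromosomal boost keeps "
      "the genome-wide per-cell total near the control's; no plant ever shows "
      "an odd CO count inside the inversion.")
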