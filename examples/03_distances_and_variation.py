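"""Align a survey, compute K2P distance summaries and variation tables.

Prints a species table in the style of a barcoding paper: sample counts,
intraspecific and interspecific distance ranges, plus the number of
diagnostic sites that individually authenticate each species.
"""

from its2barcode import (
    classify_sites,
    distance_matrix,
    find_diagnostic_sites,
    progressive_msa,
    species_summaries,
    tally_substitutions,
    variable_sites,
)
from its2barcode.simulate import SimulationConfig, simulate_dataset

records, _ = simulate_dataset(SimulationConfig(seed=1))
msa = progressive_msa(records)
dm = distance_matrix(msa)

sites = classify_sites(msa)
var = variable_sites(sites)
n_sub = sum(1 for s in var if s.kind.value == "substitution")
print(f"{msa.n_cols} alignment columns: {len(var)} variable "
      f"({n_sub} substitutions, {len(var) - n_sub} indel columns)")
tally = tally_substitutions(sites)
pretty = {"/".join(sorted(k)): v for k, v in sorted(tally.items(), key=lambda kv: -kv[1])}
print(f"substitution types: {pretty}")

diag = find_diagnostic_sites(msa)
print(f"{len({d.site for d in diag})} diagnostic sites\n")

print(f"{'species':<12} {'n':>3} {'diag':>4}  intra          inter (min-max, mean)")
for s in species_summaries(dm, msa.labels):
    n_diag = sum(1 for d in diag if d.species == s.species)
    intra = f"{s.intra.mean:.3f}" if s.intra else "   - "
    print(f"{s.species:<12} {s.n_samples:>3} {n_diag:>4}  {intra}          "
          f"{s.inter.min:.3f}-{s.inter.max:.3f} ({s.inter.mean:.3f})")

# Intraspecific means of 0.000 with interspecific means near 0.03 are the
# ideal 'barcoding gap' configuration: every query has a conspecific
# reference strictly closer than any other species.
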