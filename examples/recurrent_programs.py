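"""Recurrent-program discovery on a synthetic multi-sample cohort.

Generates three organoid-like samples sharing three expression programs
(plus one private program each), runs per-sample consensus NMF with
automatic rank selection, consolidates the top-gene signatures across
samples by Jaccard similarity, and tests the recovered recurrent programs
against the planted gene sets.
"""

import numpy as np

from periprog.gep_programs import overlap_tests
from periprog.synthetic_data import SimulationConfig, make_program_cohort
from periprog.workflows import discover_recurrent_programs

cfg = SimulationConfig(seed=7)
matrices, truth = make_program_cohort(cfg)
print(f"Cohort: {cfg.n_samples} samples x {cfg.n_cells_per_sample} cells, "
      f"{cfg.n_genes} genes; {cfg.n_shared_programs} shared + "
      f"{cfg.n_private_programs_per_sample} private program(s) per sample\n")

res = discover_recurrent_programs(matrices, n_rp=6, seed=0)
print(f"Chosen NMF ranks per sample: {res.chosen_ranks} "
      f"(true rank = {len(truth.programs_by_sample['S0'])})")

for rp in res.recurrent_programs:
    samples = sorted({s for s, _ in rp.members})
    print(f"RP{rp.rp_id}: {len(rp.members)} member signatures from {samples}, "
          f"{len(rp.rp_genes)} genes (>= 1/3 of members)")
print(f"-> {len(res.multi_sample)} recurrent programs span multiple samples; "
      "these are the cohort-shared expression states\n")

# hypergeometric overlap of recovered RP gene sets against the planted blocks
planted = {f"planted{p}": set(g) for p, g in enumerate(truth.program_genes)}
recovered = {f"RP{rp.rp_id}": rp.rp_genes for rp in res.multi_sample}
ov = overlap_tests(recovered, planted, universe=cfg.n_genes)
best = ov.loc[ov.groupby("rp")["p"].idxmin()]
print(best[["rp", "reference", "intersection", "p", "p_adj"]].to_string(index=False))
print("-> each multi-sample RP overlaps one planted shared program at "
      "vanishing hypergeometric P")
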