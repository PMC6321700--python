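"""Ka/Ks contrast between two ortholog cohorts under different selection.

Simulates 120 ortholog pairs evolving under strong purifying-to-neutral
pressure (omega = 0.90, the "missing gene" condition) and 120 near-
neutral pairs (omega = 0.99, the genome-wide condition), estimates
Ka/Ks per pair with the NG86 counting method, and runs a Welch t-test
between the group means. A mean ratio below 1 indicates purifying
selection; the test asks whether the two cohorts differ.
"""

from avirescue.evolution import compare_groups, kaks_pair
from avirescue.synthetic_data import (
    SimulationConfig,
    evolve_species_orthologs,
    simulate_reference_geneset,
)


def cohort(omega: float, seed: int, n: int = 120) -> list[float]:
    cfg = SimulationConfig(
        n_genes=n, n_species=1, species=("sp",), omega=omega,
        divergence=0.3, p_lost=0.0, p_hidden=0.0, seed=seed,
    )
    ref = simulate_reference_geneset(cfg)
    orth = evolve_species_orthologs(ref, cfg)
    refs = {r.id: str(r.seq) for r in ref.cds}
    ratios = [
        kaks_pair(refs[rec.id], str(rec.seq)).ratio for rec in orth.species_cds["sp"]
    ]
    return [r for r in ratios if r is not None]


missing = cohort(omega=0.90, seed=1)
genome_wide = cohort(omega=0.99, seed=2)
res = compare_groups(missing, genome_wide)
print(f"mean Ka/Ks, 'missing'-like cohort   (true omega 0.90): {res.mean_a:.3f} (n={res.n_a})")
print(f"mean Ka/Ks, genome-wide-like cohort (true omega 0.99): {res.mean_b:.3f} (n={res.n_b})")
print(f"Welch t = {res.t_statistic:.2f}, two-sided p = {res.p_value:.2e}")
print("A significant difference with both means < 1 reproduces the pattern of")
print("recovered 'missing' genes being under somewhat stronger purifying selection.")
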