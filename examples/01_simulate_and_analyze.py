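"""End-to-end differential analysis on a simulated two-state experiment.

Generates a three-peptide apo vs ligand dataset in which pep01 exchanges
40% faster when ligand-bound (pep02/pep03 are unchanged), then runs both
statistical methods and prints the per-peptide estimates. A positive
estimate means the ligand-bound state takes up more deuterium (in %D
units); small p-values flag peptides whose structure dynamics change upon
binding.
"""

from hdxstat import ModelSpec, analyze_dataset, build_dataset
from hdxstat.simulate import PeptideSpec, SyntheticSpec, simulate_dataset

peptides = tuple(
    PeptideSpec(
        peptide_id=f"pep{i:02d}", base_mz=480.0 + 60 * i, charge=1, n_exchangeable=8,
        rate_a=5e-5, rate_b=5e-5 * (1.4 if i == 1 else 1.0),
    )
    for i in (1, 2, 3)
)
sim = simulate_dataset(SyntheticSpec(peptides=peptides, seed=42))

dataset = build_dataset(sim.peaklists, "apo", "ligand")
results = analyze_dataset(dataset, ModelSpec(response="percentD", min_time_s=600.0))

print(f"{'peptide':8} {'method':10} {'est(%D)':>8} {'95% CI':>18} {'p':>9}")
for r in results:
    ci = f"[{r.ci_low:6.2f}, {r.ci_high:6.2f}]"
    print(f"{r.peptide_id:8} {r.method:10} {r.estimate:8.3f} {ci:>18} {r.p_value:9.2e}")
print("\npep01 carries the induced kinetic shift; the other two are true nulls.")
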