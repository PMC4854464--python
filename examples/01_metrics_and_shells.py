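"""Per-residue metrics and the rate gradient in distance shells.

Generates one synthetic enzyme with a buried catalytic site and a planted
rate-distance gradient, assembles the per-residue site table (rate K, WCN,
RSA, distance d), and summarizes mean rates in 5-Angstrom shells around
the active site.
"""

from enzgrad import SyntheticConfig, shell_summary, synthesize

protein = synthesize(SyntheticConfig(n_sites=300, seed=42))
table = protein.site_table

print(f"protein {table.protein_id}: {table.n_sites} sites, "
      f"{int(table.df['is_catalytic'].sum())} catalytic")
print(table.df[["chain", "residue_number", "K", "wcn", "rsa", "d", "shell"]]
      .head(5).to_string(index=False))

print("\nmean rate by distance shell (shell 0 = catalytic residues):")
summary = shell_summary(table)
for shell in summary.shells:
    print(f"  shell {shell}: n={summary.counts[shell]:4d}  "
          f"mean K = {summary.mean_K[shell]:.3f}")

print("\nRates rise with shell index: residues near the catalytic site are")
print("the most conserved (lowest K), and the planted gradient fades with")
print("distance, as in real enzymes.")
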