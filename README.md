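# enzgrad

Conservation gradients toward catalytic residues in enzymes.

Catalytic residues are the most conserved sites in an enzyme, but their
influence does not stop at the active site: site-specific evolutionary
rates tend to *increase approximately linearly* with the distance to the
nearest catalytic residue, over most of the protein. `enzgrad` is a
library for quantifying that long-range functional constraint on protein
structures and for separating it from the classical structural
determinants of sequence variation — local packing and solvent exposure.
It is aimed at molecular-evolution and structural-bioinformatics
researchers who have a structure, a catalytic-site annotation, and
per-site rate estimates (e.g. Rate4Site output), or who want to study the
method itself on fully synthetic data.

## What it computes

For every residue *i* (side-chain geometric center; Cα for glycine):

- **K** — site-specific relative evolutionary rate, normalized so each
  protein has mean 1 (K < 1 ⇒ conserved);
- **WCN** — weighted contact number, WCNᵢ = Σ_{j≠i} 1/r²ᵢⱼ (packing);
- **RSA** — Shrake–Rupley accessible surface area (probe 1.4 Å) divided
  by the residue type's Gly-X-Gly maximum (exposure); residues covalently
  linked across chains get RSA 0;
- **d** — Euclidean distance to the nearest catalytic residue (d = 0 ⇔
  catalytic);
- interface flags: RSA(single chain) − RSA(assembly) ≥ 0.10.

On top of the per-residue table it provides:

- 5 Å **distance shells** (shell 0 = catalytic, shell 5 ends at 27.5 Å)
  with per-shell rate summaries and a binned-mean smoother;
- the seven per-protein **linear models** K ~ d, K ~ RSA, K ~ WCN,
  K ~ RSA + d, K ~ WCN + d, K ~ WCN + RSA, K ~ WCN + RSA + d, with R²,
  ΔR² from adding d, per-shell residuals, and stratification by
  active-site burial (core/intermediate/surface) and protein size;
- **active-site recovery**: the optimized-distance scan (each residue in
  turn is a candidate gradient origin; the reference maximizing the R² of
  K ~ distance-to-reference is the putative active site) against a
  max-WCN control, scored by distance-to-truth, Fisher's exact test and
  ROC/AUC;
- a **synthetic generator**: excluded-volume residue clouds, planted
  buried/surface/random catalytic sites, and rates drawn from a linear
  law in d, WCN and RSA plus Gaussian noise — so the whole pipeline is
  testable offline.

## Worked example

```python
from enzgrad import SyntheticConfig, shell_summary, synthesize

protein = synthesize(SyntheticConfig(n_sites=300, seed=42))
summary = shell_summary(protein.site_table)
for shell in summary.shells:
    print(f"shell {shell}: n={summary.counts[shell]:4d}  mean K = {summary.mean_K[shell]:.3f}")
```

prints

```
shell 0: n=   3  mean K = 0.227
shell 1: n=  20  mean K = 0.527
shell 2: n=  72  mean K = 0.777
shell 3: n= 126  mean K = 1.034
shell 4: n=  79  mean K = 1.299
```

— the planted gradient: catalytic residues (shell 0) evolve at ~0.23× the
protein average, and rates rise monotonically with distance. Fitting the
models on ten such proteins (`examples/02_rate_models.py`):

```
mean R^2 across 10 synthetic proteins (one protein, one vote):
  K~d             28.5%
  K~WCN+RSA       22.1%
  K~WCN+RSA+d     39.9%
adding d to K~WCN+RSA gains 17.8 percentage points of R^2.
```

Distance explains rate variation that packing and exposure cannot. The
`examples/` directory holds one short script per capability; each prints
its numbers with a line on what they mean. A thin CLI mirrors the
library (`enzgrad simulate|metrics|fit|shells|recover|reproduce`), e.g.

```
enzgrad metrics --structure 1dhf.pdb --annotation 1dhf_catalytic.csv \
    --rates 1dhf.r4s --rate-format rate4site --out out/
```

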