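# screenkit

Analytics for small-molecule anticancer screening campaigns, built as an
importable Python library. It covers the computational spine of a modern
phenotype-to-target study of a drug lead — here the fluorinated
salicylanilide amide NSC765598
(N-(2,4-difluorophenyl)-2′,4′-difluoro-4-hydroxybiphenyl-3-carboxamide,
C₁₉H₁₁F₄NO₂) — from raw plate signals to target-level statistics:

- **`molgraph`** — MDL V2000 molfile/SDF input, Hill-notation formulas, and
  perception of implicit hydrogens, rings and benzenoid aromaticity.
- **`descriptors`** — graph-derivable drug-likeness descriptors: molecular
  weight, Lipinski H-bond donor/acceptor counts, Ertl topological polar
  surface area (TPSA), fraction Csp³, rotatable bonds, and the rule-of-five
  verdict (logP and molar refractivity are consumed as external inputs).
- **`dose_response`** — NCI60 five-dose screen mathematics: piecewise
  percent growth PG = 100·(Ti−Tz)/(C−Tz) for Ti ≥ Tz and 100·(Ti−Tz)/Tz
  otherwise, the GI50 / TGI / LC50 endpoint concentrations where PG crosses
  +50 / 0 / −50 (linear interpolation in log₁₀ concentration, with "> max" /
  "< min" censoring), and per-panel potency summaries.
- **`compare_fp`** — COMPARE-style activity fingerprints (−log₁₀ molar
  potency per cell line) and Pearson correlation of a seed compound against
  a library over pairwise-complete cell lines.
- **`target_consensus`** — Venn membership and mean-reciprocal-rank
  consensus over heterogeneous target predictors (Pa/Pi pairs,
  probabilities, pharmacophore fit scores).
- **`genomics_stats`** — alteration frequencies, index-gene co-occurrence
  enrichment (log₂ percentage ratio, two-sided Fisher exact p,
  Benjamini–Hochberg q), Wilcoxon rank-sum comparison, median-split
  grouping, Kaplan–Meier curves, and the Mantel–Cox log-rank test with the
  O/E hazard ratio and its log-scale 95% CI.
- **`network_enrich`** — PPI-graph summaries (nodes, edges, average degree
  2E/N, mean local clustering), hub identification, and hypergeometric
  gene-set enrichment with the p < 10⁻⁵ / count ≥ 3 / strength ≥ 2 filter.
- **`synthetic_data`** — seeded generators for every input class with
  machine-readable ground truth, plus constructed study-shaped fixtures.
- **`pipeline`** — an end-to-end orchestrator producing one CSV per stage
  and a deterministic text report.

## Worked example

```python
from screenkit.molgraph import load_fixture
from screenkit.descriptors import compute_descriptors, lipinski

mol = load_fixture("nsc765598")          # packaged V2000 molfile
d = compute_descriptors(mol, logp=4.867901, molar_refractivity=87.77)
print(d.mw, d.n_hbd, d.n_hba, d.tpsa, d.frac_csp3, d.n_rotatable)
print(lipinski(d).passed)
```

prints

```
361.29 2 3 49.33 0.0 4
True
```

i.e. a molecular weight of 361.29 g/mol, two H-bond donors (the phenolic
O–H and amide N–H), three Lipinski acceptors (1 N + 2 O; the four fluorines
are excluded), a TPSA of 49.33 Å² (20.23 hydroxyl + 17.07 carbonyl + 12.03
amide N–H), no sp³ carbons, four rotatable bonds (biphenyl link,
aryl–carbonyl, amide C–N, N–aryl), and a clean rule-of-five pass — the
drug-likeness profile of an orally plausible lead.

The `examples/` directory holds one short narrative script per capability
(dose–response endpoints, COMPARE ranking, target consensus, tumor
genomics, network enrichment, full pipeline); each prints the numbers it
computes and a line on what they mean.

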