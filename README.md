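# oilqsar

QSAR/QPAR toolkit for a 50-compound essential-oil larvicide dataset
(terpenes, terpenoids and related phenolics tested against *Culex*
mosquito larvae and pupae). The package provides:

- **`oilqsar.graph`** — SMILES parsing (via RDKit) into a hydrogen-depleted
  molecular graph, plus BFS all-pairs topological distance matrices.
- **`oilqsar.library`** — the packaged 50-compound library with curated
  SMILES and experimental LC50 values (III/IV instar and pupae, 95% CIs),
  including a validator that flags the transcription anomalies present in
  the source tables without rejecting them.
- **`oilqsar.descriptors`** — constitutional counts (nCs, nCt, nCconj,
  nR=C*, nRCO, nArOH, nOH, H-bond donors/acceptors, nROR), topological
  indices (Balaban J, E-state TIE, unipolarity/centralization/variation,
  Balaban centric BAC + lopping centric Lop, radial centric ICR, eccentric
  connectivity CSI, eccentricity sum ECC, Kier flexibility PHI) and
  physicochemical descriptors (Ui, Hy, TPSA, Moriguchi MlogP implemented
  from the original 13-parameter regression, Ghose–Crippen AlogP/AMR via
  RDKit, charge aggregates).
- **`oilqsar.reactivity`** — Koopmans-theorem frontier-orbital descriptors
  (I, A, gap, χ, μ, η, σ, ω) and a consistency validator for the packaged
  orbital-energy table.
- **`oilqsar.probit`** — maximum-likelihood probit dose–response fitting
  (Fisher scoring), LC50/LCp estimation with Fieller confidence intervals
  (delta-method fallback), Abbott control-mortality correction and a
  Pearson heterogeneity factor.
- **`oilqsar.regression` / `oilqsar.ga`** — OLS with leave-one-out Q²
  (hat-matrix identity) and a deterministic binary-chromosome genetic
  algorithm for descriptor-subset selection (fitness = Q², subset-size cap,
  tournament selection, uniform crossover, elitism), plus an exhaustive
  search oracle.
- **`oilqsar.published`** — refits of the twelve published QSAR/QPAR models
  on the packaged printed-table fixtures, reported next to the printed
  statistics. Note: the printed R²/Q² values are **not** recoverable from
  the printed inputs (the printed F statistics imply much larger models
  than the printed descriptor lists); the refits report the honest values.
- **`oilqsar.simulate`** — seeded generators for WHO-style grouped binomial
  bioassays and planted-model descriptor/activity matrices.

## CLI

```bash
oilqsar descriptors mols.smi --set all --out descriptors.csv
oilqsar reactivity orbitals.csv          # or no arg: validate the fixture
oilqsar probit assay.csv --quantile 0.5  # CSV columns: dose,n,dead
oilqsar qsar-fit --descriptors nCt,nCconj,nRCO,nROR --endpoint IV
oilqsar ga-search --endpoint IV --seed 1 --generations 100
oilqsar simulate --kind bioassay --seed 1 --out sim.csv
oilqsar reproduce --endpoint IV --seed 1 --out reports/
```

Exit codes: 0 success, 2 usage error, 3 data validation failure,
4 non-convergence.

## Data files

`src/oilqsar/data/` contains the compound library
(`compounds.csv`) and verbatim transcriptions of the printed source tables
(`table1_activity.csv`, `table3_constitutional.csv`, `table5_physchem.csv`,
`table6_reactivity.csv`, `table7_topological.csv`). Printed anomalies
(inconsistent confidence intervals, a handful of rows whose descriptor
values correspond to a different isomer than the named compound) are
preserved as printed and surfaced by validators.
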