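# herbnet

Network-pharmacology inference for multi-herb formulas.

Traditional multi-herb preparations act through many compounds hitting
many protein targets at once, which makes their mechanism hard to read
off any single assay. `herbnet` implements the standard
network-pharmacology chain for such formulas — built around the six-herb
Erxian decoction and its candidate disease, polycystic ovary syndrome —
as a tested, reusable pipeline:

1. **ADME screen** — candidate compounds are kept when predicted oral
   bioavailability OB ≥ 30 % and drug-likeness DL ≥ 0.18 (both
   inclusive).  DL is the Tanimoto similarity
   `f(A, B) = A·B / (|A|² + |B|² − A·B)` between a compound's molecular
   descriptor vector A and a reference descriptor profile B summarizing
   known drugs.  OB values and descriptor vectors are consumed as
   inputs; the package does not train QSAR models or compute descriptors
   from structures.
2. **Compound–target network** — a bipartite graph in which a compound's
   degree is its number of distinct protein targets.
3. **PPI topology and hubs** — degree, unnormalized shortest-path
   betweenness, eccentricity, radius, diameter and characteristic path
   length; *hubs* are nodes whose degree strictly exceeds **twice the
   median** degree of their scope (the partition for bipartite graphs,
   the whole node set for PPI graphs).
4. **Drug–disease overlap** — node-set intersection of the drug-target
   network with a disease gene set, with per-gene provenance
   (drug-only / disease-only / shared).
5. **Enrichment** — upper-tail hypergeometric over-representation of the
   shared genes in GMT gene sets, Benjamini–Hochberg FDR across tested
   terms, and Cohen's-kappa grouping of redundant terms (single-linkage
   components at κ ≥ 0.4).

Because the original database exports behind such studies are not
redistributable, a first-class synthetic-data module generates every
pipeline input with *planted* ground truth (pass fractions, overlap
counts, hubs, enriched terms), so each stage's statistical behavior is
testable offline.  The package ships the 70-compound screened-ingredient
table of the Erxian decoction as a fixture.

## Worked example

```python
from herbnet import load_table1, filter_compounds
from herbnet.topology import select_hubs_from_degrees

table = load_table1()                      # 70 screened compounds
kept, rejected = filter_compounds(table)   # OB >= 30, DL >= 0.18
print(len(kept), len(rejected))
# 70 0

degrees = {r.compound_id: r.degree for r in table}
threshold, hubs = select_hubs_from_degrees(degrees)
print(threshold, len(hubs), hubs[:3])
# 18.0 13 ['C28', 'C13', 'C26']
```

All 70 packaged compounds clear the screen (the table is the
post-screen set).  The median of the 70 compound degrees is 9, so the
hub threshold is 18, and exactly 13 central compounds exceed it — led by
C28 (quercetin, 153 targets), C13 (kaempferol, 63) and C26 (luteolin,
57).

The same analysis from the shell:

```sh
herbnet simulate --seed 7 --outdir sim/        # synthetic study bundle
herbnet run --config pipeline.yaml --outdir results/
herbnet enrich --query genes.txt --gmt terms.gmt --out enrich.tsv
```

A full synthetic run at the study's scale (981 candidate compounds, 247
targets, 262 disease genes) reports `n_kept=70`, `n_shared=50` and
recovers every planted enriched term, matching the generator's truth
record.

## Layout

- `src/herbnet/io.py` — TSV/SIF/GMT/gene-list readers and writers, the
  packaged compound table
- `src/herbnet/adme.py` — Tanimoto similarity, drug-likeness, OB/DL
  filter, database-catalog intersection
- `src/herbnet/network.py` — CT / PPI / disease networks, overlap
  mapping
- `src/herbnet/topology.py` — path statistics, betweenness, hub rule
- `src/herbnet/enrichment.py` — hypergeometric test, BH FDR, kappa
  grouping
- `src/herbnet/simulate.py` — seeded generators with planted truth
- `src/herbnet/pipeline.py`, `src/herbnet/cli.py` — orchestration and
  the `herbnet` command

See `docs/methods.md` for the model details, parameter defaults and
known limitations.
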