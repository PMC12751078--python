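# ppiconserve

Tools for consolidating protein–protein interaction (PPI) databases and
quantifying the evolutionary conservation and structural coverage of the
interactions they hold.

Public PPI resources (BioGRID, DIP, IntAct, mentha, MINT, SIGNOR, BioPlex,
STRING, …) curate overlapping but strikingly inconsistent sets of
interactions, concentrated on a handful of model organisms.  `ppiconserve`
provides a tested pipeline for asking, of any collection of releases:

* **How concordant are they?**  Snapshots are harmonized to primary
  accessions and compared on `(canonical pair, taxid)` keys via exclusive
  (UpSet-style) membership signatures and the Szymkiewicz–Simpson overlap
  coefficient, |A∩B| / min(|A|, |B|).  A greedy identity-clustering stage
  (Needleman–Wunsch identity, CD-HIT-style shorter-sequence denominator)
  remaps snapshots onto sequence-cluster representatives to test whether
  disagreement is an identifier artifact.
* **Which interactions are evolutionarily conserved?**  Each protein is
  mapped to an ortholog group (OrthoDB-style IDs); an interaction's
  *conservation span* is the number of distinct species in which the same
  unordered group pair was observed.
* **Are conserved interactions structurally solved?**  Per span level *s*,
  structure coverage is compared with the non-conserved (span-1) baseline
  through the 2×2 odds ratio OR = (a/b)/(c/d) with the Haldane–Anscombe
  0.5 correction on zero cells and a log-normal 95% CI; conserved pairs
  without any PDB complex form a ranked "remaining to be solved" list,
  and the conserved network (span ≥ 5 by default) is exported with
  solved/unsolved edge annotation.
* **How rigid is a predicted complex?**  Multi-model ensembles are
  analysed with Kabsch superposition, per-residue Cα RMSF about an
  iterative mean structure, inter-chain contact frequencies (8 Å Cα–Cα
  default), and the TM-score
  TM = max over superpositions of (1/L_t) Σᵢ 1/(1 + (dᵢ/d0)²),
  d0 = 1.24 (L_t − 15)^⅓ − 1.8, with the standard fragment-seeded
  iterative refinement (TM > 0.5: same fold).

Because real database releases cannot ship with a package, the
`synthetic` module generates every input format with planted ground truth
(containment relations, span distributions, per-span odds ratios, cluster
labels, flexibility profiles) so that each stage is testable end to end.

## Worked example

Run the end-to-end demo on synthetic inputs:

```bash
ppiconserve demo --out run --seed 1
```

This generates eight database snapshots over a shared pair universe (with
MINT drawn as a strict subset of IntAct at 11% of its size), cross-species
orthology records, a structure index with planted odds ratios, a sequence
family set and a two-chain conformational ensemble, then runs every
analysis stage.  Inspecting the outputs:

```text
$ python -c "import json; print(json.load(open('run/overlap/overlap_summary.json'))['median_overlap_coefficient'])"
0.2353112208962781
$ head -4 run/conserve/enrichment.tsv
level  n_solved  n_unsolved  proportion  odds_ratio  ci_low     ci_high  fisher_p
1      40        775         0.0490798   1           0.637987   1.56743  1
2      77        220         0.259259    6.78125     4.49901    10.2212  4.68368e-21
3      75        76          0.496689    19.1201     12.1879    29.9951  4.62938e-40
```

The low median off-diagonal overlap coefficient (~0.24) reflects the
planted poor concordance between releases; the enrichment table shows the
solved fraction rising from ~5% for non-conserved pairs to ~50% at span
3, with odds ratios (6.8, 19.1, …) recovering the planted 6/22/… within
sampling error.  `run/conserve/unsolved.csv` ranks conserved group pairs lacking
structures, `run/conserve/network.graphml` holds the conserved network
with solved/unsolved edge flags, and `run/ensemble/rmsf.tsv` /
`contacts.tsv` / `tm_scores.json` report the flexibility analysis
(planted interface contact recovered at frequency 0.3000).

Every subcommand (`overlap`, `cluster`, `conserve`, `enrich`, `network`,
`ensemble`, `simulate`) can also be run on your own files via a YAML
config; see `ppiconserve --help` and the module docstrings.

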