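# gainscan

Tools for localizing where a protein family gained a new function, built
around the computational evidence chain used to place the origin of the
vertebrate visual-cycle enzymes (RPE65, LRAT) in the last common ancestor
of jawless and jawed vertebrates:

1. **Distance phylogenetics** — complete-deletion column filtering,
   p/Poisson protein distances, neighbor-joining trees, and nonparametric
   bootstrap supports from column resampling.
2. **Lineage rate contrast** — a branch length calibrated against a
   divergence time gives a rate in substitutions/site/My; the ratio of two
   calibrated branches quantifies the burst of evolution that accompanies
   gain of function.
3. **Type-II functional-divergence sites** — columns conserved *within*
   each of two clades but fixed for *different* residues *between* them,
   scored per column as T = f_A · f_B · [cons_A ≠ cons_B] with a
   permutation p-value over label re-partitions (exact by enumeration when
   feasible) and reported as score = −log10 p, so "score > 3" means
   p < 0.001.
4. **Critical-residue neighborhood enrichment** — whether predicted
   diverged sites cluster within ±w residues of known critical residues,
   tested with a one-sided hypergeometric (Fisher) tail over the window
   union.
5. **Peptide mass fingerprinting** — in-silico tryptic digestion with
   modification forms (N-terminal acetylation, pyroglutamate from Gln,
   Met oxidation), monoisotopic masses, and tolerance matching of observed
   MALDI-TOF centroids with sequence-coverage reporting.
6. **Reciprocal-best-hit orthology** — strict (rank-1 both ways) and
   relaxed (reciprocation within the top k) calls from paired BLAST-style
   hit tables, with family-level absence calls.

A seeded synthetic-data module generates two-clade families with planted
type-II columns, noisy centroid peak lists, and paired hit tables with a
planted ortholog map, so the full pipeline is testable offline.

## Worked example

```python
from gainscan import datasets
from gainscan.divergence import CladePartition, type2_site_scores
from gainscan.massfinger import coverage
from gainscan.synthetic_data import simulate_family

# published MALDI-TOF fingerprint of the 537-residue lamprey RPE65 band
df = datasets.load_pmf_table()
diff = df.centroid_mass - df.theoretical_mass
print(f"peaks within 0.1 Da: {(diff.abs() < 0.1).sum()}/17")
ranges = {(r.start, r.end) for r in df.itertuples()}
cov = coverage(ranges, datasets.PMF_PARENT_LENGTH)
print(f"sequence coverage: {100 * cov:.1f}% -> reported {round(100 * cov)}%")

# recover planted type-II sites from a simulated two-clade family
aln, truth = simulate_family(seed=1)
prof = type2_site_scores(aln, CladePartition(truth.clade_a, truth.clade_b),
                         n_perm=9999, seed=2)
print(f"detected type-II columns: {sorted(prof.sites_above(3.0))}")
print(f"planted type-II columns:  {sorted(truth.type2_columns)}")
```

prints

```
peaks within 0.1 Da: 17/17
sequence coverage: 29.1% -> reported 29%
detected type-II columns: [27, 47, 51, 53, 63, 78, 127, 159, 169, 200]
planted type-II columns:  [27, 47, 51, 53, 63, 78, 127, 159, 169, 200]
```

Every observed centroid sits within the 0.1 Da matching tolerance of its
theoretical peptide; the matched peptide ranges cover 29% of the protein —
the level of agreement that identifies the immunoreactive band as RPE65.
On the simulated family, every planted clade-diagnostic column is
recovered at p < 0.001 with no false positives.

The same operations are exposed on the command line (`gainscan njtree`,
`gainscan diverge`, `gainscan digest`, `gainscan pmf-match`,
`gainscan rbh`, `gainscan simulate`, ...); see `gainscan --help`.

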