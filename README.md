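# gliometab

Analysis toolkit for **intraoperative-microdialysis metabolomics** of
gliomas: from catheter-annotated peak-area matrices to ranked fold-change
lists, metabolite-set enrichment, paired exact differential abundance,
sample clustering, and a CSF-based plasma-contamination analysis — with a
synthetic cohort generator so every stage can be tested without patient
data.

## The problem

During glioma surgery, microdialysis catheters placed in contrast-enhancing
tumour (E, blood–brain-barrier disrupted), non-enhancing tumour (NE) and
adjacent brain (B) recover extracellular fluid whose untargeted LC–MS
metabolite profile reflects each region's microenvironment. Cohorts are
tiny (a handful of cases, 1–3 catheters each) and inter-patient
heterogeneity is large, so the analysis is built around *within-case*
contrasts:

- **Ranked lists.** For each case and contrast (e.g. E vs B), every
  analyzable metabolite gets a fold change `FC = value(E)/value(B)` of
  median-normalized peak areas; the list is ordered from the most
  tumour-associated (rank 1) to the most brain-associated (rank N), with
  rank score `log2 FC`.
- **Metabolite-set enrichment.** A set *S* (e.g. one case's top-35
  tumour metabolites, or a bloody-CSF signature) is scored against another
  case's ranked list with the weighted Kolmogorov–Smirnov running sum:
  a hit at position *i* adds `|s_i|^p / N_R`, a miss subtracts
  `1/(N − N_H)`; `ES` is the signed maximum deviation. Since single
  catheter pairs have no sample labels to permute, the null redraws the
  set's positions uniformly from the list (metabolite permutation);
  `NES = ES / mean(|ES_null|, same sign)`, with a nominal permutation p
  and a ratio-of-tails FDR q across all (list, set) pairs. Estimates of
  exactly 0 are reported as `<1e-05`.
- **Paired exact testing.** With n = 7–9 pairs, the Wilcoxon signed-rank
  p-value is computed from the exact distribution of the rank sum over all
  2^n sign assignments (zero differences discarded, midranks for ties) —
  the attainable minimum two-sided p is `2/2^n`: **0.0039** at n = 9 and
  **0.0156** at n = 7. Significance combines `p ≤ 0.05` with a mean
  fold-change cutoff (≥ 2 or ≤ 0.5).
- **Plasma contamination.** A bloody-vs-clean CSF fold-change list (one
  paired sample pair, or pooled top/bottom heme quartiles) defines which
  metabolites track blood content; its top/bottom-35 sets are queried
  against each case's tumour contrast to test whether the enhancing
  metabolome is plasma-derived.

## Worked example

```python
from gliometab import (median_normalize, presence_filter, paired_contrast_table,
                       volcano_table, build_sets_from_list, permutation_null)
from gliometab.preprocess import normalizable_subset
from gliometab.synthetic import fixture_small
from gliometab.pipeline import _case_lists

matrix, annotation, truth = fixture_small()        # 9 cases, 200 metabolites
micro = [s for s in matrix.sample_ids
         if annotation.table.loc[s, "location"] != "CSF"]
sub, _ = normalizable_subset(matrix.copy_with(matrix.values[micro]))
filtered, n_kept = presence_filter(median_normalize(sub), 0.90)
print(f"{n_kept} metabolites present in >=90% of {filtered.n_samples} catheters")

results, _ = paired_contrast_table(filtered, annotation, "E/B")
top = max(results, key=lambda r: r.mean_fc)
print(f"top E/B metabolite: {top.metabolite_id} "
      f"(mean FC {top.mean_fc:.2f}, p {top.p_two_sided:.4f}, n={top.n_pairs})")
counts = volcano_table(results).attrs["class_counts"]
print(f"E/B: {counts['up']} up, {counts['down']} down, {counts['ns']} ns")

lists = _case_lists(filtered, annotation, "E/B")
top_set, _ = build_sets_from_list(lists[0], k=35)
r = permutation_null(lists[1], top_set, seed=1)
print(f"{top_set.name} in {lists[1].name}: ES {r.es:.3f}, "
      f"NES {r.nes:.2f}, p {r.display_p()}")
```

prints

```
160 metabolites present in >=90% of 25 catheters
top E/B metabolite: met_0001 (mean FC 98.60, p 0.0039, n=9)
E/B: 51 up, 11 down, 98 ns
case01:E/B__top35 in case02:E/B: ES 0.885, NES 2.10, p <1e-05
```

`met_0001` is the cohort's planted GAA-analogue (a tumour-produced
creatine precursor with an extreme enhancing-tumour effect): its ~100-fold
mean E/B ratio is recovered at the attainable-minimum p for nine
concordant pairs, and one case's tumour signature is strongly positively
enriched in another case's ranked list.

The same run is available end-to-end from a config file:

```bash
gliometab run --config config.yaml --out outputs/
```

with `config.yaml` naming either input files (`inputs: {matrix: ...,
annotation: ...}`) or a simulation (`simulate: {}`), plus an explicit
`seed`. Subcommands (`simulate`, `normalize`, `filter`, `rank`,
`make-sets`, `enrich`, `diff`, `cluster`, `csf`, `report`) run each stage
standalone on intermediate files (RNK ranked lists, GMT/GMX sets, TSV
tables).

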