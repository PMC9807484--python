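# mirameta

Evidence synthesis for microRNA biomarker discovery in type 2 diabetes (or
any case/control condition profiled across heterogeneous small studies).
The package turns a corpus of per-study dysregulation-event counts and a
pair of microRNA–target evidence ledgers into a priority-ranked biomarker
list, via:

1. **Event-count random-effects meta-analysis.** Each substudy contributes
   a 2×2 table (dysregulated vs not, in case and control arms) giving a log
   odds ratio `y = ln(ad/bc)` with variance `v = 1/a + 1/b + 1/c + 1/d`
   (Haldane–Anscombe +0.5 on any zero cell). Between-substudy variance τ²
   is estimated **twice** — by REML and by the Paule–Mandel fixed point
   (the empirical-Bayes estimator) — and a microRNA is significant only if
   its Bonferroni-adjusted Wald p is below α under *both* estimators with
   matching direction. Subgroup analyses stratify by tissue, blood fraction
   (serum/plasma/PBMC/whole blood) and platform; sensitivity analyses
   re-run at sample-size thresholds n ≥ 25 and n ≥ 50.
2. **Publication-bias diagnostics.** Begg's rank-correlation test (exact
   permutation p at k ≤ 8 without ties, enumerated through the Mahonian
   distribution of Kendall's S), Egger's regression (intercept z test), and
   Duval–Tweedie trim-and-fill (L₀ estimator) with re-pooling — a candidate
   must stay significant after correction.
3. **Interaction-evidence filtering.** A miRNA→gene pair is *robust* iff it
   keeps ≥ 2 distinct experimental PMIDs after retracted articles are
   struck **and** also appears among the top-percentile bioinformatic
   predictions.
4. **Pathway impact analysis.** Signed pathway graphs are augmented with
   repression edges from robust microRNAs; perturbation factors solve
   `(I − B)·PF = ΔE` with `B[i,j] = β(j→i)/outdeg(j)`, the accumulation
   `Acc = PF − ΔE` sums to the impact statistic `tA`, whose permutation p
   (`pAcc`) combines with the hypergeometric over-representation p
   (`pORA`) as `pG = c − c·ln c`, `c = pORA·pAcc`, BH-adjusted across
   pathways.
5. **Biomarker ranking.** Candidates (significant, direction-consistent,
   perturbation inputs on a significant target pathway, surviving bias
   correction where tested) are ranked: blood-detectable first, then by
   breadth of significance, adjusted p, effect size, name.

A synthetic-data generator plants ground truth (effect microRNAs, robust
interactions, a target pathway among matched nulls) so every stage is
testable without any external database.

## Worked example

```bash
python examples/02_publication_bias.py
```

prints

```
Begg (exact): Kendall tau = 1.0000, two-sided p = 0.0028
...
trim-and-fill: k0 = 1 imputed study at y = 1.35
  pooled logOR 2.520 (naive) -> 2.325 (corrected), p = 2.5e-05
```

With six substudies whose effects grow strictly with their variances,
Kendall's τ = 1 and the exact two-sided p is 2/6! = 0.0028 — only the
identity and the reversal among 720 orderings are that extreme. In the
asymmetric funnel `(0.0, 3.0, 3.1, 3.2, 3.3)` trim-and-fill estimates one
suppressed study, imputes its mirror image at 1.35 about the trimmed centre
2.325, and the corrected pooled logOR drops from 2.52 to 2.33 but remains
significant. The other scripts in `examples/` walk through the
meta-analysis table, the evidence filter, perturbation propagation and the
full pipeline; `examples/05_full_pipeline.py` ends with the planted
pathway at adjusted pG = 3×10⁻⁵ versus 1.0 for every matched null and all
five planted microRNAs in tier 1.

The same pipeline runs from a shell against TSV inputs:

```bash
mirameta simulate --config run.yaml   # or point the config at your own TSVs
mirameta all --config run.yaml
```

writing one TSV per stage plus `summary.json` and a `manifest.json` with
the config hash, seed and input content hashes (identical reruns produce
identical manifests).

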