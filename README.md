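# phenoprio

Benchmarking disease phenotype networks for network-propagation gene
prioritization.

## The problem

A disease phenotype network (DPN) is a weighted network whose nodes are
diseases (OMIM entries, say) and whose edge weights score how similar two
diseases look clinically. Because phenotypically similar diseases tend to be
caused by genes whose proteins sit close together in the protein–protein
interaction (PPI) network, a good DPN can drive *guilt-by-association* gene
prioritization: propagate evidence from the known genes of similar diseases
through the PPI network and rank the candidates.

Different DPNs (MeSH-based cosine matrices, HPO-based information-content
scores, …) come on different scales, some asymmetric and unbounded. This
package provides the full apparatus to put them on a common footing and
measure, by cross-validation, which one prioritizes disease genes better —
for methodologists comparing similarity measures, and for anyone who wants a
self-contained, download-free testbed for propagation-based prioritization.

## The method

1. **Symmetrization.** An asymmetric similarity is averaged with its
   transpose: `Sim_sym(A,B) = (Sim(A→B) + Sim(B→A)) / 2`.
2. **Normalization** into [0, 1] by one of four maps (`S` the raw score):
   - Lin: `2·S(A,B) / (S(A,A) + S(B,B))`
   - Sqrt: `S(A,B) / √(S(A,A)·S(B,B))`
   - Maxmin: `(S(A,B) − S_min) / (S_max − S_min)`
   - Tanimoto: `S(A,B) / (S(A,A) + S(B,B) − S(A,B))`
3. **Logistic calibration** `L(x) = 1 / (1 + e^{cx + d})` with `d = ln 9999`
   (so `L(0) = 10⁻⁴`) and `c < 0` chosen by cross-validation; this
   suppresses the bulk of weak similarities while keeping strong ones.
4. **PRINCE propagation** over the PPI network: with
   `W_norm = D^{-1/2} A D^{-1/2}` and a prior `Y` (1 on known *seed* genes of
   the query disease, otherwise the calibrated similarity of the most
   similar disease each gene is associated with),

       F(t) = α · W_norm · F(t−1) + (1 − α) · Y,   F(1) = Y,   α = 0.9.

   Genes are ranked by the converged (or iteration-capped) `F`.
5. **Leave-one-out cross-validation.** Every disease–gene association is
   held out in turn and re-predicted; summaries are the mean rank ratio
   (MRR, % — lower is better), the number of targets ranked 1st, and TPR@k
   for k ∈ {5, 10, 30}. Two aligned DPNs can also be blended entrywise
   (`p·A + (1−p)·B`) before calibration, and compared via a 2×2 concordance
   table and the relative-network-mean diagnostic.

A synthetic-data generator plants exactly the structure the method exploits
(disease modules whose genes are PPI-proximal, higher within-module
phenotype similarity), so the whole pipeline runs and is tested without any
external files.

## Worked example

```python
import phenoprio as pp

cfg = pp.SynthConfig(n_genes=200, n_diseases=40, n_modules=5, seed=0)
ppi, phenonet, dgmap = pp.generate(cfg)
net = pp.logistic_transform(pp.normalize(phenonet, "tanimoto"), c=-15)

records = pp.loocv(dgmap, net, pp.Form.SYMMETRIC, ppi, mode="all")
report = pp.compute_report(records)
print(f"MRR {report.mrr_percent:.2f}%  top-ranked {report.top_count}/{report.n_targets}  "
      f"TPR@30 {report.tpr_at[30]:.1f}%")
```

prints

```
MRR 8.11%  top-ranked 2/81  TPR@30 87.7%
```

i.e. across the 81 held-out associations the true gene sits on average in
the top 8.11 % of the ~200 candidates, 2 are recovered at rank 1, and 87.7 %
land in the top 30. Replacing the phenotype network by a label-permuted
null (`pp.permute_labels`) degrades this to MRR 13.77 % and TPR@30 77.8 % —
the gap is the guilt-by-association signal. To rank genes for one disease:

```python
query = "D0000"
ranked = pp.prioritize(query, dgmap, net, pp.Form.SYMMETRIC, ppi)
# -> [("G0000", 0.2617), ("G0055", 0.2373), ("G0002", 0.2139), ...]
```

The same steps are available from the shell (`phenoprio simulate`,
`normalize`, `combine`, `logistic`, `prioritize`, `loocv`, `run`); see
`phenoprio --help` and `docs/methods.md` for the file dialects and the YAML
pipeline configuration.

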