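# mixcna

Three-state copy-number aberration (CNA) calling in **heterogeneous tumor
samples** from aggregate allele signals, plus the supporting machinery: a
ground-truthed subclone-mixture simulator, a stromal-fraction solver, an
exhaustive demonstration that general subclone de-mixing is non-unique, and
an RNA-seq scanner for within-exon allelic-imbalance fluctuations that mark
subclonal somatic variants.

## Who this is for

Anyone analyzing SNP-array or sequencing signals from samples that are
mixtures of cell populations — tumor biopsies with stromal contamination
and multiple subclones — where exact integer copy numbers of any single
component are not recoverable from the aggregate signal.

## The method in brief

Per SNP, the aggregate allele channels (a, b) are transformed to B-allele
frequency and total-DNA enrichment

    β = b / (a + b),    ρ = (a + b) / 2,    log R = log2 ρ,

so a normal diploid locus sits at β ∈ {0, ½, 1}, ρ = 1. The **M-measure**
of a SNP is the window average (default W = 20 SNPs) of

    f(β) = |sin 2πβ|

over the heterozygous-band SNPs of the window: f vanishes at the normal
β values and rises steeply once an aberration in a fraction of cells pulls
heterozygous SNPs off ½. A SNP is called aberrant when M exceeds a cutoff
(default 0.1) *or* when its windowed mean log R is significantly below 0
(one-sided z-test; this rescues hemizygous deletions carried by nearly all
cells, which silence the β signal). Aberrant SNPs are labeled **loss** or
**gain** by the sign of the windowed mean log R. A three-state Viterbi
decoder over the same evidence is included (`viterbi_3smm`).

Calls are scored with the three-class mean balanced accuracy
½(TP/P + TN/N) averaged over gain/loss/normal — the AUCROC at the
operative point of a thresholded classifier.

For a binary mixture (one tumor component plus diploid stroma at fraction
x), deletion loci satisfy c̄ = 2x + m(1 − x) with tumor copy number
m ∈ {0, 1}, so x = (c̄ − m)/(2 − m); the mode of the pooled per-locus
candidates recovers x (`infer_mixing_coefficient`). For three or more
components `enumerate_demixings` shows by exhaustive search that exact
reconstructions are not unique — which is why calling is reduced to three
states in the first place.

## Worked example

```python
import numpy as np
from mixcna import (MixtureSpec, simulate_dataset, classify_three_state,
                    auc_roc_three_class, infer_mixing_coefficient)

# stroma at 30% plus two subclones at 2(1-α)/3 and (1-α)/3, 10,000 loci
spec = MixtureSpec(alpha=0.3, n_subclones=2, seed=42)
profile, truth = simulate_dataset(spec)
calls = classify_three_state(profile)
print(f"three-class AUCROC: {auc_roc_three_class(calls, truth):.3f}")
for s in ("gain", "loss", "normal"):
    print(f"  {s:6s} called {int((calls.state==s).sum()):5d}"
          f"  true {int((truth.state==s).sum()):5d}")

# stromal-fraction recovery is defined for binary mixtures
bprofile, _ = simulate_dataset(MixtureSpec(alpha=0.3, n_subclones=1, seed=42))
bcalls = classify_three_state(bprofile)
sol = infer_mixing_coefficient(bprofile, np.flatnonzero(bcalls.state == "loss"))
print(f"stromal fraction estimate: {sol.x_hat:.3f} from {sol.n_loci_used} loci")
```

prints

```
three-class AUCROC: 0.967
  gain   called  2689  true  3000
  loss   called  3019  true  3000
  normal called  4292  true  4000
stromal fraction estimate: 0.305 from 2011 loci
```

The classifier recovers the dominant-component state of 97% (balanced) of
loci despite 30% stromal dilution and two overlapping subclones; the gain
deficit is mostly the weaker subclone's gain blocks, whose allelic
imbalance is faintest. The mixing-coefficient estimate lands within half a
histogram bin of the true 0.30.

The same pipeline is available from the shell:

```sh
mixcna simulate --alpha 0.3 --subclones 2 --seed 42 --out signal.tsv --truth-out truth.bed
mixcna classify --in signal.tsv --out calls.tsv --segments-out segments.bed
mixcna demix    --in calls.tsv --out demix.json
mixcna evaluate --alphas 0.1,0.3,0.5 --reps 20 --subclones 2 --out eval.csv
mixcna rnaseq-imbalance --in counts.tsv --exons exons.bed --out rnaseq_calls.tsv
```

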