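# protlen

Statistical analysis of **proteome length distributions**: which simple
probability law best describes how long a species' proteins are, and what
the deviations from that law say about genome annotation quality and
protein evolution.

Given a protein FASTA per species, the package

1. builds the **non-redundant set** (exact duplicates and contained
   subsequences removed; optional keyword filtering of transposon-like
   annotations) with a curation log;
2. computes **descriptive statistics** (mean, SD, percentiles of length in
   aa), pooled gene-based GC content from CDS FASTA, and cross-species
   Pearson correlations (protein number vs mean size, GC vs size);
3. fits four candidate laws to lengths z in 0 < z < 1,500 by maximum
   likelihood — gamma with free shape θ, gamma with θ fixed at 2,
   log-normal, and the hypoexponential sum of two exponentials — and ranks
   them by **AIC = 2k − 2 log L**;
4. tests the classical hypothesis that the gamma shape is exactly 2, by
   pooling per-species shape MLEs θ̂_j (SEs from the information matrix,
   [I⁻¹]_θθ = θ/(θψ′(θ) − 1)) into θ̄ ~ N(θ, Σσ_j²/J²);
5. fits a **Pareto tail** (z > 1,500 aa) with closed-form estimators and a
   χ² goodness-of-fit test;
6. correlates each amino acid's percentage composition with protein length
   (per species, aggregated by taxon group);
7. computes analytic **random-ORF expectations** under GC-biased base
   composition (stop probability 3/64 at 50% GC; expected ORF 1/p codons:
   ~21 aa at 50% GC, 14 aa at 35%, 31 aa at 60%) plus a geometric
   simulator;
8. flags **annotation anomalies**: interior-mode vs monotone-suspect
   histograms, sharp minimum-length cutoffs (20–60 aa window), and
   single-length excess peaks called against the AIC-best model;
9. generates **synthetic proteomes** with known ground truth (length law,
   composition-length tilt, injected duplicates, gene-family peaks,
   transposon tags) so the whole pipeline is testable offline.

See `docs/methods.md` for the models, conventions and their rationale.

## Worked example

```python
from protlen import AnalysisConfig, SyntheticSpec, simulate_proteome, run_species
from protlen.pipeline import report_to_dict

spec = SyntheticSpec(
    species_code="DEMO",
    model="gamma_free",
    params_dict={"shape": 2.3, "rate": 0.006},   # mean 383 aa
    n=20_000, seed=7, min_length=30,
    peaks=((332, 500),),          # a gene-family peak at 332 aa
    duplicates=(5, 3),            # 5 exact + 3 subsequence duplicates
    transposon_fraction=0.01,
)
proteome, ledger = simulate_proteome(spec)
report = run_species(proteome, AnalysisConfig(keywords=("transposon",)))
d = report_to_dict(report)
```

With this seed the report contains:

```text
curation    n_raw 20508, duplicates removed 8, keyword removed 200, kept 20300
summary     mean 383.1 aa, sd 246.7, median 332.0
best model  gamma_free  (shape 2.505, rate 0.00658, AIC 273807.8)
shape SE    0.0234
annotation  interior_mode, sharp_cutoff=True (min length 30)
peaks       position 332: observed 534 vs expected 36.4, excess score 82.5
```

Reading it: curation removed exactly the 8 injected redundant records and
the 200 transposon-tagged ones; the AIC winner is the free-shape gamma (the
generating family); the classifier sees the healthy interior mode but also
the hard 30-aa cutoff the spec imposed; and the injected 332-aa gene-family
peak is called at 82 standard deviations above the fitted model — the
signature a real mammalian olfactory-receptor expansion leaves in a length
histogram. The fitted shape (2.50) sits above the generating 2.3 because
the peak injection and the 30-aa cutoff both distort the bulk fit — the
same reason model-relative diagnostics are needed on real proteomes.

The same pipeline is scriptable from the shell:

```bash
protlen simulate spec.json --out-fasta demo.fasta --out-ledger ledger.json
protlen report demo.fasta --out report.json
protlen orf-expect --gc 0.35,0.5,0.6
protlen cross SP1.fasta SP2.fasta ... --groups groups.tsv
```

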