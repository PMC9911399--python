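# hitseq

Simulation and analysis of **HiTS-Eq** experiments — high-throughput
sequencing of equilibrium binding.  An RNA pool carrying every possible
7-mer (16,384 variants) is equilibrated with an RNA-binding protein at a
series of concentrations; sequencing the *unbound* pool turns per-variant
depletion into relative binding affinities.  `hitseq` is written for
biochemists and computational biologists who want to analyse such data — or
prototype the analysis on fully synthetic experiments with known ground
truth.

The pipeline:

1. **simulate** — ground-truth affinity landscapes (bimodal, or additive
   with pairwise couplings) and realistic 50-nt reads with UMIs, index
   barcodes, PCR duplication and sequencing errors;
2. **count** — parse reads (constant region matched within 1 mismatch,
   no gaps), demultiplex by 3-nt index, collapse UMIs, count 7-mers;
3. **affinity** — estimate relative association constants K_A,rel from
   depletion, with the cognate reference 5'-UGCAUGU pinned to 1:

       K_A,rel(v) = (R·(1 + E') − 1) / E',   R = n_ref(E)/n_v(E),  E' = E/K_ref

   per concentration (median across the series), or a Poisson
   maximum-likelihood fit of each variant's whole depletion curve with a
   jointly estimated pool-renormalisation factor (`--estimator global-fit`);
4. **aggregate** — project 7-mer affinities onto the 1,024 5-mers through
   their 48 (or fewer) 7-mer contexts, with box-plot summaries and
   flanking-nucleotide effects;
5. **model** — position-weight-matrix (PWM) and pairwise-coupling (PWC)
   regressions of ln K_A,rel under reference coding, with the cognate
   withheld so its residual exposes a distinct binding mode; couplings with
   |t| > 3.5 are flagged;
6. **report** — affinity histograms, a Gaussian-mixture bimodality test,
   top-40 sequence logos, percentile ranks, the max/median specificity
   ratio, and RBNS R-score normalisation for cross-protein comparison.

Quadratic (ligand-depletion) and competitive-inhibition isotherm fits for
individual substrates are included (`fit_isotherm`, `fit_competition`).

## Worked example

```python
import numpy as np
import hitseq as hq

landscape = hq.make_landscape(seed=1)          # 16,384 7-mers, bimodal Kd
config = hq.SimulationConfig(depth=1_000_000, error_rate=1e-3, seed=3)

counts, libraries = hq.run_simulation(landscape, config)
table = hq.estimate_affinities(counts, libraries, estimator="global-fit")

truth = np.log(landscape.kd_of("UGCAUGU") / landscape.kd)
est = np.log(table.ka.reindex(landscape.variants).to_numpy())
ok = (landscape.kd >= 2.0) & (landscape.kd <= 19740.0) & np.isfinite(est)
print("reference K_A,rel:", table.ka["UGCAUGU"])
print("recovery r:", round(np.corrcoef(truth[ok], est[ok])[0, 1], 3))

report = hq.assess_bimodality(table.ka[table.ka > 0], floor=1e-6)
print("mixture components preferred:", report.preferred)
print("cognate percentile:", round(hq.percentile_rank(table.ka, "UGCAUGU"), 1))
```

prints

```
reference K_A,rel: 1.0
recovery r: 0.98
mixture components preferred: 2
cognate percentile: 99.8
```

The reference is exactly 1 by construction; `r = 0.98` says the pipeline
recovers ln-affinities across the informative range (Kd between the lowest
and highest protein concentrations) at the precision limit of the counting
experiment; the mixture test detects the bimodal affinity distribution — a
small high-affinity cognate population well separated from the bulk — and
the cognate sequence ranks at the top of all 16,384 variants.

The same steps run from the shell:

```bash
hitseq simulate --seed 1 --depth 100000 --out-dir sim/
hitseq count --fastq sim/reads.fastq --index-table sim/libraries.tsv --out counts.tsv
hitseq affinity --counts counts.tsv --index-table sim/libraries.tsv --out affinity.tsv
hitseq aggregate --affinity affinity.tsv --out fivemers.tsv
hitseq model --affinity affinity.tsv --model pwc --baseline UGCAUGU --out pwc.tsv
hitseq report --affinity affinity.tsv --out-prefix report
```

## Layout

```
src/hitseq/
  simulate.py     landscapes, equilibrium partitioning, read simulation, FASTQ
  reads.py        parsing, demultiplexing, UMI collapse, normalisation
  affinity.py     K_A,rel estimators and isotherm fits
  kmers.py        5-mer contexts, aggregation, flanking effects
  models.py       PWM / pairwise-coupling regressions
  specificity.py  histograms, bimodality, logos, percentiles, R-score scaling
  pipeline.py     end-to-end drivers
  plotting.py     optional matplotlib helpers
  cli.py          `hitseq` command-line interface
docs/methods.md   model, estimators, generator, numerical choices
```

See `docs/methods.md` for the underlying model, the estimator derivations,
what the synthetic generator does and does not emulate, and known
limitations.
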