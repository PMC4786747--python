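# cladewane

Diversity, disparity and extinction dynamics of fossil clades.

`cladewane` is an analysis pipeline for palaeobiologists studying how a
clade — the motivating case is the last ichthyosaurs, fish-shaped marine
reptiles that vanished in the early Late Cretaceous — waned and went
extinct.  From a rooted cladogram, a discrete morphological character
matrix (NEXUS), a stratigraphic range table (first/last appearance ages in
Ma) and per-bin occurrence and environmental series, it computes:

* **Timescaled trees** by the *basic* rule (each node at the oldest
  descendant first-appearance, the minimum-ghost-lineage dating) and the
  *equal* rule (zero branches share the nearest positive ancestral branch
  equally), for any set of input trees;
* **Diversity curves**: taxic richness per bin, and the phylogenetic
  diversity estimate including ghost lineages, with median and 95%
  interval across the tree × method set;
* **Disparity through time**: weighted mean pairwise dissimilarity on the
  raw matrix, and the sum of variances of principal-coordinate scores on a
  tips-plus-unambiguous-ancestors matrix (Fitch/Farris most-parsimonious
  reconstruction), both with bootstrap CIs;
* **Rates**: per-bin cladogenesis, extinction, per-lineage extinction
  (100 × extinctions / lineages) and turnover, plus parsimony-based
  character change rates per branch;
* **Ecomorph guilds**: Ward clustering of scaled trait tables with
  multiscale-bootstrap AU support (z(r) = v√r + c/√r, AU = 1 − Φ(v − c));
* **Extinction timing**: occurrence-frequency tests — P(zero finds in N
  formations) = (1 − f)^N and its inversion — and constant-recovery
  stratigraphic range extensions (classical R((1−C)^(−1/(H−1)) − 1) and
  Poisson −ln(1−C)/λ);
* **Environmental correlation**: generalized differencing, pairwise tests,
  and AR(1)-GLS model comparison by AICc with Akaike weights, over full
  and truncated bin windows.

A first-class synthetic-clade generator (birth–death trees, Mk characters,
Poisson fossil preservation, planted trait guilds, AR(1) environments)
provides ground truth for every stage, so the whole pipeline is testable
without any external data.

## Worked example

Run the numbered analysis scripts from the repository root; each is a thin
driver over the library and writes its tables under `results/`:

```bash
python analysis/01_simulate_clade.py
python analysis/03_diversity_curves.py
python analysis/07_extinction_timing.py
```

which prints (seed 1):

```
simulated clade: 266 true taxa, 121 preserved; matrix 121x88 (45.8% missing) -> results/synthetic
wrote results/diversity.csv (32 bins)
MAE vs true standing diversity: taxic 14.06, phylogenetic 7.78
published-case occurrence tests:
  prob_zero_f019_n26 = 0.004
  freq_bound_p05_n26 = 0.109
  freq_bound_p50_n26 = 0.026
  recovery_rate_120_formations_157p3_my = 0.76
  expected_formations_4p1_my = 3.13
```

Reading the numbers: less than half the simulated taxa are ever preserved,
and the ghost-lineage-corrected diversity curve halves the mean absolute
error against the true standing diversity compared with raw range counts
(14.1 → 7.8 lineages per bin) — the reason phylogeny-informed diversity
estimates are worth the trouble in poorly sampled intervals.  The
occurrence tests give the published-case answer: with 26 suitable
formations and a prior 19% occurrence frequency, total absence has
probability 0.004, and the group would need to be rarer than 10.9% (or
2.6%, to make absence actually likely) per formation to be hiding rather
than extinct.

The remaining scripts (`02` timescaling, `04` disparity, `05` rates, `06`
guilds, `08` environmental correlation) follow the same pattern, and the
same stages are available as a CLI (`cladewane simulate|timescale|
diversity|ecomorph|extinction-test|run`) driven by a JSON config.

## Layout

```
src/cladewane/      library: strat, charmatrix, trees, timescale, diversity,
                    disparity, ancstates, rates, ecomorph, extinction,
                    envcorr, simulate, pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 08_correlate)
tests/              pytest suite with brute-force oracles and calibration runs
docs/methods.md     models, conventions, defaults and their rationale
```
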