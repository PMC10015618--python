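# mescan

Speciation-genomics pipeline for quantifying how chromosome fission and
fusion rearrangements affect gene flow between a pair of sister
species.  It combines:

* **Blockwise-SFS demographic inference.**  Short blocks of 64 callable
  intergenic bases are tallied, for one sampled diploid per species,
  into joint counts of four unpolarized mutation types (hetA, hetB,
  hetAB, fixed), truncated at k<sub>max</sub>=2 per type.  Exact
  probabilities of these counts are computed under a two-epoch
  structured coalescent — strict divergence (DIV) or isolation with
  migration (IM) with a constant effective migration rate
  m<sub>e</sub> — and blocks are combined into a composite likelihood
  lnCL = Σ<sub>k</sub> n<sub>k</sub> log p<sub>k</sub>.  Model fits
  maximize lnCL over (N<sub>e</sub><sup>A</sup>, N<sub>e</sub><sup>B</sup>,
  N<sub>e</sub><sup>anc</sup>, T, m<sub>e</sub>); a parametric bootstrap
  under the DIV fit calibrates ΔlnCL between the nested models.
* **Windowed m<sub>e</sub> scans.**  Consecutive blocks are tiled into
  windows, each scored over a precomputed likelihood grid with the
  split time fixed; *barrier windows* are those where
  lnCL(m<sub>e</sub>=0) exceeds lnCL at the background grid value.
* **Rearrangement detection and polarization.**  Filtered whole-genome
  alignments yield rearrangement points (junctions and implicated
  chromosome ends); single-copy markers shared by the two species and
  an outgroup are collapsed into co-occurrence sets and a maximum
  parsimony search reconstructs the ancestral karyotype and assigns
  fissions/fusions to branches of ((A,B),O).
* **Permutation tests** linking the two: chromosome label switching
  (do rearranged chromosomes have lower mean m<sub>e</sub> and more
  barrier windows?) and adjacent-window sampling (is m<sub>e</sub>
  further reduced within 1 Mb of rearrangement points?).

A seeded synthetic-data module (coalescent block tallies via msprime,
VCF+BED emission, and three-taxon marker tables generated by applying
fission/fusion events along a tree) makes the whole pipeline testable
without any external data.

## Worked example

The numbered drivers under `analysis/` run the pipeline end to end on
synthetic data (`python analysis/01_simulate_data.py`, then 02 … 07),
writing tables under `results/`.  Fitting both demographic models to a
60,000-block tally simulated at the best-fit IM parameters
(`analysis/04_fit_demography.py`) prints:

```
    model           lnCL          ne_a          ne_b       ne_anc   split_time           me
      DIV -175010.900520 254041.390488 703855.052246 1.420855e+06 1.182969e+06          NaN
IM_into_A -174245.716058 169918.279571 876033.163116 1.149095e+06 2.135175e+06 1.815269e-07
observed dlnCL(IM - DIV) = 765.2
bootstrap null dlnCL max = 26.87 over 5 replicates; observed 765.2 rejects DIV
```

The IM fit recovers the simulated truth (N<sub>e</sub> 0.171/0.880/1.116
×10⁶, T = 2.202×10⁶ generations, m<sub>e</sub> = 1.811×10⁻⁷ ≙ 0.124
effective migrants/generation), while the misspecified DIV fit absorbs
the migration into a younger split — and its parametric bootstrap shows
the observed ΔlnCL is far outside the no-migration null.  Downstream,
the window scan + permutation drivers print:

```
80 windows scanned; MCL me equals truth in 100%
barrier fraction: rearranged 0.92 vs non-rearranged 0.00
ancestor: 16 chromosomes; events per branch (fissions, fusions): {'A': (2, 5), 'B': (0, 2)}
label switching: mean-me deficit 2.55e-07 (p = 0.0005999); barrier excess 0.917 (p = 0.0005999)
adjacent windows: me deficit near points 2.53e-08 (p = 0.001543; 39066 permutations discarded)
```

i.e. the planted m<sub>e</sub> deficit on rearranged chromosomes, the
planted rearrangement history, and the extra reduction near
rearrangement points are all recovered with one-tailed permutation
support.

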