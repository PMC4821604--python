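# nucshift

Differential nucleosome-positioning analysis for MNase-seq, built for the
question: *which nucleosomes need an ATP-dependent sliding remodeler to stay
where they are?* Given paired mononucleosome fragment libraries from a
wild-type (WT) and a remodeler-mutant condition (the motivating system is
*Drosophila* hemocytes lacking the NURF-specificity subunit), the package

* estimates a continuous **nucleosome dyad density** per condition
  (fragment midpoints, Gaussian-kernel smoothed, per-million normalized),
* calls **nucleosome shifts** in 50-bp windows
  (`log2fc = log2((n_mut+1)/(n_wt+1))` on depth-normalized counts,
  |log2fc| > 2), merges them into regions, summarizes their distribution
  over gene features and lays them on a **Hilbert curve** for
  whole-chromosome views,
* fits the **+1 nucleosome position** and **nucleosome repeat length (NRL)**
  from TSS-anchored averaged profiles — the +1 is the first qualifying
  density maximum downstream of the TSS, and the NRL is the least-squares
  slope of peak offset on nucleosome index over peaks +1..+5,
* classifies nucleosome organization around TF and insulator sites into
  **five archetypes** (occupied / adjacent / entry-exit / depleted /
  barrier) and measures **NDR half-widths** at insulator summits, with
  cofactor stratification (e.g. ±CP190 at ≥ 50 summit reads),
* and ships a fully parameterized **synthetic fragment generator** whose
  ground truth makes every stage testable without any sequencing download.

It is aimed at chromatin genomicists who have fragment BED files, bedGraph
ChIP signals and gene/site tables, and want the differential-positioning
analyses behind a typical remodeler-mutant study in one tested library with
a thin CLI.

## Worked example

Simulate 200 active genes under the package's paired study-condition presets
(WT: +1 at +132 bp, NRL 175 bp; mutant: +123 bp, 170 bp; positional fuzz
15 bp, 30 dyads per nucleosome), then recover those parameters from the
fragments alone:

```python
from nucshift import simulate, density, arrays

bundle = simulate.generate(simulate.single_gene_config("active", n=200, seed=1))
tracks = {c: density.density_from_fragments(bundle.fragments[c], bundle.chrom_sizes)
          for c in ("wt", "mut")}
fit_wt = arrays.fit_condition(tracks["wt"], bundle.annotations, condition="wt")
fit_mut = arrays.fit_condition(tracks["mut"], bundle.annotations, condition="mut")
print(fit_wt.summary())
print(arrays.compare_conditions(fit_wt, fit_mut).summary())
```

which prints

```
Nucleosome array fit (wt)
==============================================
+1 dyad position (bp)                 132.0
peaks detected                            6
NRL, regression slope (bp)           175.00
NRL std. err. (bp)                     0.00
intercept (bp)                       -43.00
r-squared                            1.0000
peaks used                                5
peak offsets (bp): +132, +307, +482, +657, +832, +1007
Array comparison (mut - wt)
per-index dyad shift:
  +1: -9.0 bp
  +2: -14.0 bp
  +3: -19.0 bp
  +4: -24.0 bp
  +5: -29.0 bp
  +6: -34.0 bp
NRL difference: -5.00 bp
first index with |shift| < 5 bp: none
```

The WT +1 sits at +132 bp with a 175-bp repeat (r² = 1 on the averaged
profile); in the mutant the whole array is pulled toward the TSS — −9 bp at
the +1, growing by the 5-bp repeat-length difference at each downstream
index — exactly the generating architecture.

The same analyses run from the shell on files:

```bash
nucshift simulate --preset-bundle study-defaults --seed 1 --out bundle/
nucshift density  --fragments bundle/fragments_wt.bed --chrom-sizes bundle/chrom.sizes \
                  --out wt.density.bedGraph
nucshift shifts   --wt bundle/fragments_wt.bed --mut bundle/fragments_mut.bed \
                  --chrom-sizes bundle/chrom.sizes --out shifts.bed
nucshift arrays   --wt-density wt.density.bedGraph --mut-density mut.density.bedGraph \
                  --chrom-sizes bundle/chrom.sizes --annotations bundle/annotations.tsv \
                  --group-by activity --out fits.tsv
nucshift classify-sites --wt-density wt.density.bedGraph --mut-density mut.density.bedGraph \
                  --chrom-sizes bundle/chrom.sizes --sites bundle/sites.tsv --out cls.tsv
```

Subcommands `profile`, `stratify` and `hilbert` cover anchored averaging,
cofactor splits and Hilbert-plot matrices. See `docs/methods.md` for the
models, parameter defaults and the generator's assumptions.

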