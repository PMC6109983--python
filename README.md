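# dremap

Histone-mark-based mapping of regulatory elements and their hormone-response
dynamics, for compact insect genomes.

## The problem

Steroid hormones such as the insect molting hormone (20-hydroxyecdysone,
"20E") reprogram transcription through *cis*-regulatory elements. Given
two-condition ChIP-seq of three histone marks (H3K4me1, H3K4me3, H3K27ac)
plus receptor (EcR) binding, RNA-seq RPKM values and gene models, the
questions are: where are the promoters and enhancers, which of them are
active, which change when the hormone is added, what do they regulate, and
does the receptor bind them through its response-element motif?

`dremap` implements that analysis as a tested, reusable library:

* **Genome annotation** — the genome is tiled into five exclusive regions
  (promoter-TSS = [TSS−1 kb, TSS+200 bp), exon, intron, TTS = the mirrored
  [TTS−200 bp, TTS+1 kb) window, intergenic; priority
  promoter > exon > intron > TTS > intergenic), and every peak is assigned
  by its summit position.
* **Element calls** — a *promoter element* is an H3K4me3 peak whose summit
  lies within 1.5 kb of a TSS; a *distal regulatory element* (DRE, the
  enhancer candidate) is an H3K4me1 peak whose summit lies more than 1.5 kb
  from every TSS. An element is *active* when it overlaps (≥ 1 bp) an
  H3K27ac peak. Each element carries its nearest gene by summit-to-TSS
  distance.
* **Dynamics** — regions are fold-classified between conditions on
  library-scaled mean coverage: with
  `fold = (treated + ψ) / (control + ψ)` (pseudocount ψ = 0.5 density
  units), `fold > 2` is *increased*, `fold < 0.5` *decreased*, else
  *stable*; per-DRE H3K27ac dynamics use the at-least-twofold (≥ 2)
  boundary. Presence calls label peaks found in only one condition.
* **Expression linkage** — genes split into none / low / medium / high
  expression (RPKM < 1 = none; rank tertiles of the rest), strand-oriented
  TSS metaprofiles (±2 kb, 50-bp bins), and mean log2(RPKM+1) of nearest
  genes per element class.
* **Motif scanning** — log2-odds PWM scanning of peak sequences on both
  strands; a peak "contains" the motif when some window scores at least a
  configurable fraction (default 0.80) of the min–max score range.
* **Synthetic data** — a generator that plants all of the above (genes,
  promoters, active/poised enhancers, treated-condition H3K27ac gains,
  expression coupling, receptor peaks with response-element instances) with
  configurable jitter, dropout, decoy and depth, and writes a truth table,
  so every stage has a download-free recovery test.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
dataset (written under `scratch/`, tables under `results/`):

```bash
python analysis/01_simulate.py --seed 0
python analysis/03_call_elements.py
python analysis/04_dynamics.py
```

which prints, among other things:

```
control: 289 promoters, 599 DREs (286 active)
  recovery promoter: precision 1.000, recall 0.963 (n=300)
  recovery active_DRE: precision 0.993, recall 0.947 (n=300)
...
DREs with >=2-fold H3K27ac increase after treatment: 82/598
vs planted labels: gain sensitivity 1.000 (n=82), stable false-positive rate 0.000 (n=486)
```

Reading: from peak lists corrupted with 50-bp summit jitter, 5% dropouts
and 5% decoys, the pipeline recovers the 300 planted active enhancers with
99% precision and 95% recall; of the called DREs, 82 show an at-least
twofold H3K27ac increase after treatment, and every one of them is a
planted activation (no stable region is misclassified). The same flow is
available as a CLI (`dremap simulate`, `dremap report`, `dremap all`, …)
and as plain library calls:

```python
import dremap
ds = dremap.simulate(dremap.SimulationConfig(seed=0))
elements = dremap.call_elements(ds.peaks[("H3K4me1", "control")],
                                ds.peaks[("H3K4me3", "control")],
                                ds.peaks[("H3K27ac", "control")],
                                ds.genes, "control")
dremap.truth_compare(elements, ds.truth)
```

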