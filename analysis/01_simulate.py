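#!/usr/bin/env python
"""Generate the synthetic two-condition ChIP-seq study.

Writes the full labeled dataset (genome FASTA, GFF3 gene models, narrowPeak
lists and bedGraph coverage for H3K4me1/H3K4me3/H3K27ac in control and
hormone-treated conditions, receptor peaks, RPKM table, truth tables) under
scratch/dataset/, plus the pipeline configuration the later steps consume.
"""

import argparse
from pathlib import Path

from dremap.report import dataset_config_text
from dremap.simulate import SimulationConfig, simulate

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--noise-free", action="store_true")
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    if args.noise_free:
        cfg = cfg.noise_free()
    ds = simulate(cfg, outdir=args.outdir)
    (args.outdir / "pipeline.cfg").write_text(dataset_config_text(args.outdir))

    gains = (ds.truth.elements["dynamics"] == "gain").sum()
    print(f"dataset in {args.outdir}")
    print(f"  genome: {len(ds.scaffold_lengths)} scaffolds x "
          f"{cfg.scaffold_length:,} bp, {len(ds.genes)} genes")
    print(f"  planted: {cfg.n_active_enh} active + {cfg.n_poised_enh} poised "
          f"enhancers ({gains} gaining H3K27ac on treatment), "
          f"{len(ds.truth.ecr_peaks)} receptor peaks "
          f"({ds.truth.ecr_peaks['motif_planted'].sum()} with motif)")
    print(f"  corruption: jitter sd {cfg.summit_jitter_sd} bp, "
          f"{cfg.miss_rate:.0%} dropouts, {cfg.false_peak_rate:.0%} decoys")


if __name__ == "__main__":
    main()
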