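#!/usr/bin/env python
"""How many receptor-bound peaks contain a response-element motif?

Scans every receptor peak sequence with the bundled response-element PWM
(log2-odds, both strands, threshold 0.80 of the min-max score range),
reports the fraction with at least one hit, where receptor peaks fall
relative to called elements, and checks detection against the planted
motif flags.
"""

import argparse
from pathlib import Path

import pandas as pd

import dremap
from dremap import io as dio
from dremap.elements import call_elements
from dremap.intervals import overlap_fraction
from dremap.motifs import peaks_with_motif
from dremap.report import proportion_report

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    ap.add_argument("--threshold", type=float, default=0.80)
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    genome = dio.read_fasta(args.data / "genome.fa")
    pwm = dio.read_pwms(args.data / "ecre_motif.jaspar")[0]
    ecr = dio.read_peaks(args.data / "ecr_treated.narrowPeak")
    genes = dio.read_gene_models(args.data / "genes.gff3")

    count, fraction, table = peaks_with_motif(ecr, genome, pwm, args.threshold)
    table.to_csv(args.results / "ecr_motif_hits.tsv", sep="\t", index=False,
                 float_format="%.4f")
    print(f"{count}/{len(ecr)} receptor peaks "
          f"({proportion_report(count, len(ecr))}%) contain >=1 motif "
          f"at threshold {args.threshold}")

    peaks = {m: dio.read_peaks(args.data / f"{m}_treated.narrowPeak")
             for m in ("h3k4me1", "h3k4me3", "h3k27ac")}
    els = call_elements(peaks["h3k4me1"], peaks["h3k4me3"], peaks["h3k27ac"],
                        genes, "treated")
    for kind in ("DRE", "promoter"):
        targets = [e.interval for e in els if e.kind == kind]
        n, _ = overlap_fraction([p.interval for p in ecr], targets)
        print(f"  receptor peaks overlapping {kind}s: {n}")

    truth = dremap.TruthTable(
        pd.DataFrame(), pd.read_csv(args.data / "truth_ecr.tsv", sep="\t"))
    score = dremap.motif_recovery(table, truth)
    print(f"  vs planted flags: precision {score.precision:.3f}, "
          f"recall {score.recall:.3f} (planted n={score.n_truth})")


if __name__ == "__main__":
    main()
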