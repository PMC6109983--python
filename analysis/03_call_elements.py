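#!/usr/bin/env python
"""Call regulatory elements and verify them against the planted truth.

Promoter elements are H3K4me3 peaks with summits within 1.5 kb of a TSS;
DREs (enhancer candidates) are H3K4me1 peaks beyond 1.5 kb of every TSS;
activity = H3K27ac overlap. Also writes the TSS co-occurrence summary and
the DRE-to-nearest-TSS distance histogram.
"""

import argparse
from pathlib import Path

import pandas as pd

import dremap
from dremap import io as dio
from dremap.elements import (call_elements, cooccurrence_at_tss,
                             elements_to_frame, tss_distance_histogram)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    genes = dio.read_gene_models(args.data / "genes.gff3")
    truth_elements = pd.read_csv(args.data / "truth_elements.tsv", sep="\t")
    truth = dremap.TruthTable(truth_elements, pd.DataFrame())

    for cond in ("control", "treated"):
        peaks = {m: dio.read_peaks(args.data / f"{m}_{cond}.narrowPeak")
                 for m in ("h3k4me1", "h3k4me3", "h3k27ac")}
        els = call_elements(peaks["h3k4me1"], peaks["h3k4me3"],
                            peaks["h3k27ac"], genes, cond)
        elements_to_frame(els).to_csv(args.results / f"elements_{cond}.tsv",
                                      sep="\t", index=False)
        n_dre = sum(1 for e in els if e.kind == "DRE")
        n_act = sum(1 for e in els if e.kind == "DRE" and e.active)
        print(f"{cond}: {len(els) - n_dre} promoters, {n_dre} DREs "
              f"({n_act} active)")
        if cond == "control":
            scores = dremap.truth_compare(els, truth)
            for kind in ("promoter", "active_DRE", "poised_DRE"):
                s = scores[kind]
                print(f"  recovery {kind}: precision {s.precision:.3f}, "
                      f"recall {s.recall:.3f} (n={s.n_truth})")
        else:
            dres = [e for e in els if e.kind == "DRE"]
            counts, labels = tss_distance_histogram(dres)
            pd.DataFrame({"bin_bp": labels, "count": counts}).to_csv(
                args.results / "dre_distance_hist.tsv", sep="\t", index=False)
            co = cooccurrence_at_tss(peaks["h3k4me1"], peaks["h3k4me3"],
                                     peaks["h3k27ac"], genes)
            pd.DataFrame([co.__dict__]).to_csv(
                args.results / "cooccurrence_tss.tsv", sep="\t", index=False)
            print(f"  TSSs with both H3K4me3 and H3K27ac: {co.me3_with_ac}"
                  f"/{co.denominator_me3}")


if __name__ == "__main__":
    main()
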