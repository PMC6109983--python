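#!/usr/bin/env python
"""Do active enhancers sit next to more highly expressed genes?

Categorizes genes by RPKM (none / low / medium / high), builds TSS
metaprofiles of each mark per category, and compares mean log2(RPKM+1) of
nearest genes across element classes (active vs inactive DREs, all genes).
"""

import argparse
from pathlib import Path

import pandas as pd

from dremap import io as dio
from dremap.elements import call_elements
from dremap.expression import (categorize_expression,
                               expression_by_element_class, tss_metaprofile)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "dataset")
    ap.add_argument("--results", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    args.results.mkdir(parents=True, exist_ok=True)

    lengths = dio.read_scaffold_lengths(args.data / "scaffolds.tsv")
    genes = dio.read_gene_models(args.data / "genes.gff3")
    expr = dio.read_expression(args.data / "expression.tsv")
    cats = categorize_expression(expr, "control")
    sizes = {c: sum(1 for v in cats.values() if v == c)
             for c in ("none", "low", "medium", "high")}
    print(f"expression categories (control): {sizes}")

    for mark in ("h3k4me3", "h3k27ac", "h3k4me1"):
        track = dio.read_coverage(args.data / f"{mark}_control.bedGraph", lengths)
        prof = tss_metaprofile(track, genes, cats)
        frame = pd.DataFrame({"offset": prof.bin_centers}
                             | {c: prof.profiles[c]
                                for c in sorted(prof.profiles)})
        frame.to_csv(args.results / f"metaprofile_{mark}.tsv", sep="\t",
                     index=False, float_format="%.5g")
        central = {c: round(prof.central_bin(c), 1) for c in sorted(prof.profiles)}
        print(f"  {mark} signal at TSS by category: {central}")

    peaks = {m: dio.read_peaks(args.data / f"{m}_treated.narrowPeak")
             for m in ("h3k4me1", "h3k4me3", "h3k27ac")}
    els = call_elements(peaks["h3k4me1"], peaks["h3k4me3"], peaks["h3k27ac"],
                        genes, "treated")
    dres = [e for e in els if e.kind == "DRE"]
    classes = {
        "all_genes": [g.gene_id for g in genes],
        "all_DRE_targets": dres,
        "active_DRE_targets": [e for e in dres if e.active],
        "inactive_DRE_targets": [e for e in dres if not e.active],
    }
    by_class = expression_by_element_class(classes, expr, "treated")
    frame = pd.DataFrame(by_class).T
    frame.to_csv(args.results / "expression_by_class.tsv", sep="\t",
                 index_label="class", float_format="%.4f")
    print("mean log2(RPKM+1) per class (treated):")
    for name, vals in by_class.items():
        print(f"  {name}: {vals['mean_log2_rpkm']:.3f} "
              f"(n={vals['n_genes']} genes)")


if __name__ == "__main__":
    main()
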