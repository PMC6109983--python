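"""End-to-end pipeline driver and the machine-readable summary report.

``run_pipeline`` stitches the stages together — annotate peak summits,
call promoters/DREs, two-condition H3K27ac dynamics, expression linkage,
TSS metaprofiles and receptor-peak motif occurrence — and writes per-stage
TSV tables plus a ``summary.json`` of counts and fractions and a run log
with parameters and input checksums. Output is byte-deterministic for a
fixed configuration (no timestamps in any artifact).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import dynamics as ddyn
from . import elements as delem
from . import expression as dexpr
from . import io as dio
from . import motifs as dmot
from .intervals import (PARTITION_LABELS, IntervalIndex, TSSIndex,
                        assign_peak_region, build_partition, overlap_fraction)

MARK_KEYS = ("h3k4me1", "h3k4me3", "h3k27ac")
CONDITION_KEYS = ("control", "treated")

_PATH_KEYS = (
    ["genome", "genes", "scaffold_lengths", "expression", "pwm", "peaks.ecr.treated"]
    + [f"peaks.{m}.{c}" for m in MARK_KEYS for c in CONDITION_KEYS]
    + [f"coverage.{m}.{c}" for m in MARK_KEYS for c in CONDITION_KEYS]
)
_PARAM_KEYS = {
    "proximal_distance": 1500,
    "cooccurrence_window": 1500,
    "flank": 2000,
    "bin": 50,
    "pseudocount": 0.5,
    "motif_threshold": 0.80,
    "none_threshold": 1.0,
}
_REQUIRED = [
    "genes", "scaffold_lengths",
] + [f"peaks.{m}.{c}" for m in MARK_KEYS for c in CONDITION_KEYS]


def proportion_report(numerator: int, denominator: int) -> float | None:
    """Percentage at one decimal, rounded half-up; None for a zero denominator.

    Every fraction field in the summary report goes through this helper so
    that printed percentages are reproducible arithmetic on the two counts.
    """
    if denominator == 0:
        return None
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    paths: dict[str, str]
    params: dict[str, float]

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        """Parse a plain-text ``key=value`` configuration.

        Unknown keys are an error naming the key; missing required inputs
        are an error before any stage runs.
        """
        paths: dict[str, str] = {}
        params: dict[str, float] = dict(_PARAM_KEYS)
        base = Path(path).parent
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key in _PATH_KEYS:
                    p = Path(value)
                    paths[key] = str(p if p.is_absolute() else base / p)
                elif key in _PARAM_KEYS:
                    params[key] = float(value)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(paths, params).validated()

    def validated(self) -> "PipelineConfig":
        missing = [k for k in _REQUIRED if k not in self.paths]
        if missing:
            raise ValueError(f"missing required inputs: {missing}")
        absent = [f"{k}={v}" for k, v in self.paths.items() if not Path(v).exists()]
        if absent:
            raise FileNotFoundError(f"input files not found: {absent}")
        return self


def dataset_config_text(dataset_dir: str | os.PathLike) -> str:
    """Pipeline configuration pointing at a written simulated dataset."""
    d = Path(dataset_dir).resolve()
    lines = [
        f"genome={d / 'genome.fa'}",
        f"genes={d / 'genes.gff3'}",
        f"scaffold_lengths={d / 'scaffolds.tsv'}",
        f"expression={d / 'expression.tsv'}",
        f"pwm={d / 'ecre_motif.jaspar'}",
        f"peaks.ecr.treated={d / 'ecr_treated.narrowPeak'}",
    ]
    for m in MARK_KEYS:
        for c in CONDITION_KEYS:
            lines.append(f"peaks.{m}.{c}={d / f'{m}_{c}.narrowPeak'}")
    for c in CONDITION_KEYS:
        lines.append(f"coverage.h3k27ac.{c}={d / f'h3k27ac_{c}.bedGraph'}")
        lines.append(f"coverage.h3k4me3.{c}={d / f'h3k4me3_{c}.bedGraph'}")
        lines.append(f"coverage.h3k4me1.{c}={d / f'h3k4me1_{c}.bedGraph'}")
    # drop entries whose file was not generated (e.g. sequence-free runs)
    kept = []
    for line in lines:
        key, value = line.split("=", 1)
        if Path(value).exists() or key in ("genes", "scaffold_lengths"):
            kept.append(line)
    return "\n".join(kept) + "\n"


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig | str | os.PathLike,
                 outdir: str | os.PathLike) -> dict:
    """Execute every stage the inputs allow and write the report.

    Stages needing optional inputs (coverage tracks, genome+PWM,
    expression) are skipped cleanly when those inputs are absent; the
    summary records which stages ran.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    config.validated()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.params
    summary: dict = {"tool": {"name": "dremap", "version": __version__},
                     "parameters": dict(sorted(params.items()))}

    lengths = dio.read_scaffold_lengths(config.paths["scaffold_lengths"])
    genes = dio.read_gene_models(config.paths["genes"])
    peaks = {(m, c): dio.read_peaks(config.paths[f"peaks.{m}.{c}"])
             for m in MARK_KEYS for c in CONDITION_KEYS}
    ecr_peaks = (dio.read_peaks(config.paths["peaks.ecr.treated"])
                 if "peaks.ecr.treated" in config.paths else [])

    # --- stage 1: five-way genome partition, summit annotation -------------
    partition = build_partition(genes, lengths)
    rows = []
    all_sets = dict(peaks)
    if ecr_peaks:
        all_sets[("ecr", "treated")] = ecr_peaks
    region_summary: dict = {}
    for (mark, cond), plist in sorted(all_sets.items()):
        counts = {label: 0 for label in PARTITION_LABELS}
        for p in plist:
            counts[assign_peak_region(p, partition)] += 1
        for label in PARTITION_LABELS:
            rows.append({"mark": mark, "condition": cond, "region": label,
                         "count": counts[label],
                         "pct": proportion_report(counts[label], len(plist))})
        region_summary[f"{mark}.{cond}"] = counts
    pd.DataFrame(rows).to_csv(out / "peak_regions.tsv", sep="\t", index=False)
    summary["peak_regions"] = region_summary

    # --- stage 2: element calls per condition ------------------------------
    prox = int(params["proximal_distance"])
    elements = {}
    for cond in CONDITION_KEYS:
        els = delem.call_elements(
            peaks[("h3k4me1", cond)], peaks[("h3k4me3", cond)],
            peaks[("h3k27ac", cond)], genes, condition=cond,
            proximal_distance=prox)
        elements[cond] = els
        frame = delem.elements_to_frame(els)
        frame.to_csv(out / f"elements_{cond}.tsv", sep="\t", index=False)
        n_dre = sum(1 for e in els if e.kind == "DRE")
        n_prom = sum(1 for e in els if e.kind == "promoter")
        summary[f"elements.{cond}"] = {
            "promoters": n_prom,
            "active_promoters": sum(1 for e in els
                                    if e.kind == "promoter" and e.active),
            "DREs": n_dre,
            "active_DREs": sum(1 for e in els if e.kind == "DRE" and e.active),
        }

    # --- stage 3: co-occurrence and DRE distances (treated) ----------------
    cw = int(params["cooccurrence_window"])
    co_tss = delem.cooccurrence_at_tss(
        peaks[("h3k4me1", "treated")], peaks[("h3k4me3", "treated")],
        peaks[("h3k27ac", "treated")], genes, window=cw)
    co_int = delem.cooccurrence_intergenic(
        peaks[("h3k4me1", "treated")], peaks[("h3k4me3", "treated")],
        peaks[("h3k27ac", "treated")], partition)
    co_rows = []
    for co in (co_tss, co_int):
        for fieldname in ("me3_with_ac", "me3_without_ac",
                          "me1_with_ac", "me1_without_ac"):
            denom = co.denominator_me3 if "me3" in fieldname else co.denominator_me1
            co_rows.append({
                "context": co.context, "category": fieldname,
                "count": getattr(co, fieldname), "denominator": denom,
                "pct": proportion_report(getattr(co, fieldname), denom),
            })
    co_frame = pd.DataFrame(co_rows)
    with open(out / "cooccurrence.tsv", "w") as fh:
        fh.write("# fraction = count / denominator; TSS context counts TSSs "
                 "(denominator = all TSSs),\n"
                 "# intergenic context counts summit-intergenic peaks of the "
                 "row's own mark.\n")
        co_frame.to_csv(fh, sep="\t", index=False)
    summary["cooccurrence"] = {
        f"{r['context']}.{r['category']}": {"count": r["count"],
                                            "denominator": r["denominator"],
                                            "pct": r["pct"]}
        for r in co_rows}

    dres_treated = [e for e in elements["treated"] if e.kind == "DRE"]
    counts, labels = delem.tss_distance_histogram(dres_treated)
    pd.DataFrame({"bin": labels, "count": counts}).to_csv(
        out / "dre_distance_hist.tsv", sep="\t", index=False)
    summary["dre_distance_hist"] = dict(zip(labels, (int(c) for c in counts)))

    # --- stage 4: presence calls and H3K27ac dynamics ----------------------
    presence_summary = {}
    tss_index = TSSIndex(genes)
    for m in MARK_KEYS:
        ctrl_labels, trt_labels = ddyn.presence_calls(
            peaks[(m, "control")], peaks[(m, "treated")])
        presence_summary[m] = {
            "control_total": len(ctrl_labels),
            "treated_total": len(trt_labels),
            "control_only": ctrl_labels.count("control_only"),
            "treated_only": trt_labels.count("treated_only"),
            "overlap_pct": proportion_report(ctrl_labels.count("both"),
                                             len(ctrl_labels)) if ctrl_labels else None,
        }
    # distal H3K27ac (summit > proximal_distance from every TSS), per paper's
    # promoter-filtered dynamics view
    distal_ac = {}
    for cond in CONDITION_KEYS:
        distal_ac[cond] = [
            p for p in peaks[("h3k27ac", cond)]
            if (hit := tss_index.nearest(p.interval.scaffold, p.summit)) is None
            or abs(hit[1]) > prox]
    d_ctrl, d_trt = ddyn.presence_calls(distal_ac["control"], distal_ac["treated"])
    presence_summary["h3k27ac_distal"] = {
        "control_total": len(d_ctrl), "treated_total": len(d_trt),
        "control_only": d_ctrl.count("control_only"),
        "treated_only": d_trt.count("treated_only"),
    }
    pd.DataFrame(presence_summary).T.to_csv(out / "presence.tsv", sep="\t",
                                            index_label="mark")
    summary["presence"] = presence_summary

    have_ac_cov = all(f"coverage.h3k27ac.{c}" in config.paths
                      for c in CONDITION_KEYS)
    tracks: dict[tuple[str, str], object] = {}
    if have_ac_cov:
        for m in MARK_KEYS:
            for c in CONDITION_KEYS:
                key = f"coverage.{m}.{c}"
                if key in config.paths:
                    tracks[(m, c)] = dio.read_coverage(config.paths[key], lengths)
        pseudo = float(params["pseudocount"])
        regions = ddyn.union_regions(peaks[("h3k27ac", "control")],
                                     peaks[("h3k27ac", "treated")])
        calls = ddyn.classify_dynamics(regions, tracks[("h3k27ac", "control")],
                                       tracks[("h3k27ac", "treated")], pseudo)
        klasses = [c.klass for c in calls]
        summary["h3k27ac_region_dynamics"] = {
            "regions": len(calls),
            "increased": klasses.count("increased"),
            "decreased": klasses.count("decreased"),
            "stable": klasses.count("stable"),
            "rule": "strict twofold (fold > 2 or < 0.5)",
        }
        dre_calls = ddyn.dre_h3k27ac_dynamics(
            dres_treated, tracks[("h3k27ac", "control")],
            tracks[("h3k27ac", "treated")], pseudo)
        dre_klasses = [c.klass for c in dre_calls]
        dyn_rows = [{
            "scaffold": c.region.scaffold, "start": c.region.start,
            "end": c.region.end, "signal_control": round(c.signal_control, 4),
            "signal_treated": round(c.signal_treated, 4),
            "fold_change": round(c.fold_change, 4), "fold_class": c.klass,
        } for c in dre_calls]
        with open(out / "dre_h3k27ac_dynamics.tsv", "w") as fh:
            fh.write("# fold-class boundaries are inclusive (fold >= 2 "
                     "increased, <= 0.5 decreased); no significance test.\n")
            pd.DataFrame(dyn_rows).to_csv(fh, sep="\t", index=False)
        summary["dre_h3k27ac_dynamics"] = {
            "DREs": len(dre_calls),
            "increased": dre_klasses.count("increased"),
            "decreased": dre_klasses.count("decreased"),
            "stable": dre_klasses.count("stable"),
            "rule": "at-least-twofold (fold >= 2 or <= 0.5)",
        }

    # --- stage 5: expression linkage ---------------------------------------
    if "expression" in config.paths:
        expr = dio.read_expression(config.paths["expression"])
        cats = dexpr.categorize_expression(expr, "control",
                                           float(params["none_threshold"]))
        cat_counts = {c: sum(1 for v in cats.values() if v == c)
                      for c in dexpr.CATEGORIES}
        summary["expression_categories.control"] = cat_counts

        flank, binsize = int(params["flank"]), int(params["bin"])
        meta_summary = {}
        for m in MARK_KEYS:
            if (m, "control") not in tracks:
                continue
            prof = dexpr.tss_metaprofile(tracks[(m, "control")], genes, cats,
                                         flank, binsize)
            frame = pd.DataFrame({"offset": prof.bin_centers}
                                 | {c: prof.profiles[c] for c in sorted(prof.profiles)})
            frame.to_csv(out / f"metaprofile_{m}_control.tsv", sep="\t",
                         index=False, float_format="%.5g")
            meta_summary[m] = {c: round(prof.central_bin(c), 4)
                               for c in sorted(prof.profiles)}
        if meta_summary:
            summary["metaprofile_central_bin.control"] = meta_summary

        dre_index = IntervalIndex([e.interval for e in dres_treated])
        ac_only_genes = []
        for p in distal_ac["treated"]:
            if not dre_index.any_overlap(p.interval):
                hit = tss_index.nearest(p.interval.scaffold, p.summit)
                if hit is not None:
                    ac_only_genes.append(hit[0])
        classes = {
            "all_genes": [g.gene_id for g in genes],
            "DRE_targets": dres_treated,
            "active_DRE_targets": [e for e in dres_treated if e.active],
            "inactive_DRE_targets": [e for e in dres_treated if not e.active],
            "distal_H3K27ac_only": ac_only_genes,
        }
        by_class = dexpr.expression_by_element_class(classes, expr, "treated")
        cls_frame = pd.DataFrame(by_class).T
        with open(out / "expression_by_class.tsv", "w") as fh:
            fh.write("# mean of log2(RPKM+1) over the class's nearest genes, "
                     "deduplicated per class.\n")
            cls_frame.to_csv(fh, sep="\t", index_label="class",
                             float_format="%.5g")
        summary["expression_by_class.treated"] = {
            k: {kk: (round(vv, 4) if isinstance(vv, float) else int(vv))
                for kk, vv in v.items()}
            for k, v in by_class.items()}

    # --- stage 6: receptor peaks vs elements, motif occurrence -------------
    if ecr_peaks:
        n_on_dre, _ = overlap_fraction([p.interval for p in ecr_peaks],
                                       [e.interval for e in dres_treated])
        promoters_treated = [e for e in elements["treated"] if e.kind == "promoter"]
        n_on_prom, _ = overlap_fraction([p.interval for p in ecr_peaks],
                                        [e.interval for e in promoters_treated])
        summary["ecr_overlap"] = {
            "ecr_peaks": len(ecr_peaks),
            "overlapping_DREs": n_on_dre,
            "overlapping_promoters": n_on_prom,
        }
        if "genome" in config.paths and "pwm" in config.paths:
            genome = dio.read_fasta(config.paths["genome"])
            pwm = dio.read_pwms(config.paths["pwm"])[0]
            count, fraction, table = dmot.peaks_with_motif(
                ecr_peaks, genome, pwm, float(params["motif_threshold"]))
            table.to_csv(out / "ecr_motif_hits.tsv", sep="\t", index=False,
                         float_format="%.4f")
            summary["ecr_motif"] = {
                "peaks_total": len(ecr_peaks),
                "peaks_with_motif": count,
                "pct": proportion_report(count, len(ecr_peaks)),
                "threshold_fraction": float(params["motif_threshold"]),
            }

    checksums = {k: _sha256(v) for k, v in sorted(config.paths.items())}
    summary["inputs_sha256"] = checksums
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"dremap {__version__}\n")
        fh.write(f"numpy {np.__version__}, pandas {pd.__version__}\n")
        for k, v in sorted(params.items()):
            fh.write(f"param {k}={v}\n")
        for k, v in checksums.items():
            fh.write(f"sha256 {k} {v}\n")
    return summary
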