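"""Ground-truth-labeled synthetic datasets for the full pipeline.

The generator emulates the statistical structure of a two-condition
(control vs hormone-treated) histone-mark ChIP-seq study on a compact,
multi-scaffold insect genome:

* stranded, non-overlapping genes, each centered in its own genomic block;
* promoters carrying H3K4me3 + H3K27ac peaks over the strand-oriented
  [TSS-1kb, TSS+200bp) window, with coverage amplitude scaled by the gene's
  expression category;
* distal regulatory elements (DREs) as H3K4me1 peaks far (>1.5 kb) from
  every TSS; established *active* DREs additionally carry two flanking
  H3K27ac peaks around the nucleosome-depleted core, in both conditions;
* a configurable fraction of *poised* DREs gains a single nascent H3K27ac
  peak only in the treated condition, with coverage raised ``fold_gain``-x;
* expression positively coupled to element activity: genes nearest to an
  active DRE get a ``expression_coupling``-fold RPKM boost in both
  conditions, genes nearest to a treated-activated DRE only in the treated
  condition;
* receptor (EcR-like) peaks hosted on a subset of elements and intergenic
  blocks, with a near-consensus response-element instance planted in a
  configurable fraction of them;
* coverage = piecewise Gaussian bump densities + Poisson noise at a mean
  depth, written as bedGraph; peak lists corrupted by summit jitter,
  dropouts and decoy peaks.

Every stage draws from its own child generator of the master seed, so
datasets are bit-reproducible and stages can be regenerated independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .model import (BASES, CoverageTrack, ExpressionTable, GeneModel,
                    GenomicInterval, PWM, Peak)

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac")
CONDITIONS = ("control", "treated")
READ_LENGTH = 100   # bp per simulated sequencing tag

#: Near-palindromic nuclear-receptor response element consensus (IR1-like),
#: used only by the simulator and its tests; real analyses supply their own
#: matrix file. 13 columns, synthetic.
ECRE_CONSENSUS = "AGGTCAATGACCT"

_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(BASES)}


def ecre_pwm(consensus_count: float = 97.0, off_count: float = 1.0,
             pseudocount: float = 0.01) -> PWM:
    """The bundled synthetic response-element matrix, probability-normalized.

    Columns are homogeneous (``consensus_count`` on the consensus base,
    ``off_count`` elsewhere), so every mismatch costs the same score and
    hit/miss arithmetic reduces to counting mismatches.
    """
    w = len(ECRE_CONSENSUS)
    counts = np.full((4, w), off_count)
    for j, base in enumerate(ECRE_CONSENSUS):
        counts[_CODE[base], j] = consensus_count
    return PWM("ECRE_SYN", counts).normalized(pseudocount)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the synthetic experiment.

    Defaults are the study conditions exercised throughout the test suite:
    moderate sequencing depth (30x), 50-bp summit jitter, 5% peak dropouts
    and 5% decoy peaks, fourfold treated H3K27ac gains at 30% of poised
    DREs, fourfold expression coupling and a 40% motif-planting fraction.
    """

    seed: int = 0
    n_scaffolds: int = 6
    scaffold_length: int = 2_000_000
    block_size: int = 12_000
    n_genes: int = 300
    n_active_enh: int = 300
    n_poised_enh: int = 300
    activation_fraction: float = 0.3
    fold_gain: float = 4.0
    depth: float = 30.0
    background_fraction: float = 0.05
    summit_jitter_sd: float = 50.0
    false_peak_rate: float = 0.05
    miss_rate: float = 0.05
    n_ecr_peaks: int = 150
    ecre_plant_fraction: float = 0.4
    ecre_mutation_rate: float = 0.05
    expression_coupling: float = 4.0
    coverage_step: int = 10

    def __post_init__(self) -> None:
        for name in ("activation_fraction", "false_peak_rate", "miss_rate",
                     "ecre_plant_fraction", "ecre_mutation_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fold_gain < 1:
            raise ValueError("fold_gain must be >= 1")
        if self.scaffold_length % self.coverage_step != 0:
            raise ValueError("scaffold_length must be divisible by coverage_step")
        n_blocks = self.n_scaffolds * (self.scaffold_length // self.block_size)
        if self.n_genes + self.n_active_enh + self.n_poised_enh > n_blocks:
            raise ValueError(
                f"{self.n_genes + self.n_active_enh + self.n_poised_enh} placements "
                f"do not fit in {n_blocks} blocks; enlarge the genome")

    def noise_free(self) -> "SimulationConfig":
        """Copy with every corruption channel off (jitter, dropouts, decoys
        and motif-instance mutation); Poisson counting noise remains."""
        return replace(self, summit_jitter_sd=0.0, false_peak_rate=0.0,
                       miss_rate=0.0, ecre_mutation_rate=0.0)

    def small(self) -> "SimulationConfig":
        """Scaled-down copy for fast unit tests."""
        return replace(self, n_scaffolds=2, scaffold_length=600_000,
                       n_genes=30, n_active_enh=30, n_poised_enh=30,
                       n_ecr_peaks=20)


@dataclass
class TruthTable:
    """What the generator planted, for recovery scoring.

    ``elements``: one row per planted element (kind promoter / active_DRE /
    poised_DRE, its location and summit, dynamics label gain/stable, target
    gene and signed TSS distance, and whether a motif-bearing receptor peak
    sits on it). ``ecr_peaks``: one row per planted receptor peak with its
    host and motif-planting flag.
    """

    elements: pd.DataFrame
    ecr_peaks: pd.DataFrame


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    scaffold_lengths: dict[str, int]
    genes: list[GeneModel]
    peaks: dict[tuple[str, str], list[Peak]]   # (mark, condition) -> observed peaks
    ecr_peaks: list[Peak]                      # observed receptor peaks (treated)
    tracks: dict[tuple[str, str], CoverageTrack] = field(default_factory=dict)
    genome: dict[str, str] = field(default_factory=dict)
    expression: ExpressionTable | None = None
    truth: TruthTable | None = None
    pwm: PWM = field(default_factory=ecre_pwm)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stage])


@dataclass
class _Element:
    element_id: str
    kind: str           # promoter | active_DRE | poised_DRE
    scaffold: str
    start: int
    end: int
    summit: int
    dynamics: str       # gain | stable
    target_gene: str
    tss_distance: int
    motif_planted: bool = False


def _layout(cfg: SimulationConfig):
    """Place genes and enhancers on the block grid; derive planted peaks."""
    rng = _rng(cfg, 1)
    scaffolds = [f"scaf{i + 1}" for i in range(cfg.n_scaffolds)]
    lengths = {s: cfg.scaffold_length for s in scaffolds}
    blocks = [(s, b * cfg.block_size)
              for s in scaffolds
              for b in range(cfg.scaffold_length // cfg.block_size)]
    order = rng.permutation(len(blocks))

    genes: list[GeneModel] = []
    cursor = 0
    for i in range(cfg.n_genes):
        scaf, bstart = blocks[order[cursor]]
        cursor += 1
        length = int(rng.integers(2000, 5001))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        gstart = bstart + (cfg.block_size - length) // 2
        gend = gstart + length
        e1 = length * 3 // 10
        exons = [GenomicInterval(scaf, gstart, gstart + e1, strand),
                 GenomicInterval(scaf, gend - e1, gend, strand)]
        genes.append(GeneModel(f"g{i:04d}",
                               GenomicInterval(scaf, gstart, gend, strand), exons))
    genes.sort(key=lambda g: (g.interval.scaffold, g.interval.start))

    tss_by_scaf: dict[str, list[tuple[int, str]]] = {}
    for g in genes:
        tss_by_scaf.setdefault(g.interval.scaffold, []).append((g.tss, g.gene_id))

    def nearest_tss(scaf: str, point: int) -> tuple[str, int]:
        best = min(((abs(point - t), gid, point - t)
                    for t, gid in tss_by_scaf.get(scaf, [])), default=None)
        if best is None:
            return "", 0
        return best[1], best[2]

    elements: list[_Element] = []
    enh_centers: list[tuple[str, str, int]] = []   # (element_id, scaffold, center)
    n_enh = cfg.n_active_enh + cfg.n_poised_enh
    activated = rng.random(cfg.n_poised_enh) < cfg.activation_fraction
    for i in range(n_enh):
        scaf, bstart = blocks[order[cursor]]
        cursor += 1
        c = bstart + cfg.block_size // 2
        if i < cfg.n_active_enh:
            kind, dyn = "active_DRE", "stable"
            eid = f"enh_a{i:04d}"
        else:
            j = i - cfg.n_active_enh
            kind = "poised_DRE"
            dyn = "gain" if activated[j] else "stable"
            eid = f"enh_p{j:04d}"
        gid, dist = nearest_tss(scaf, c)
        elements.append(_Element(eid, kind, scaf, c - 600, c + 600, c, dyn, gid, dist))
        enh_centers.append((eid, scaf, c))

    for g in genes:
        scaf = g.interval.scaffold
        length = lengths[scaf]
        if g.strand == "+":
            s, e = g.tss - 1000, g.tss + 200
        else:
            s, e = g.tss - 199, g.tss + 1001
        s, e = max(0, s), min(length, e)
        elements.append(_Element(f"prom_{g.gene_id}", "promoter", scaf, s, e,
                                 g.tss, "stable", g.gene_id, 0))

    free_blocks = [blocks[order[k]] for k in range(cursor, len(blocks))]
    return lengths, genes, elements, enh_centers, free_blocks


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _expression(cfg: SimulationConfig, genes: list[GeneModel],
                elements: list[_Element]) -> ExpressionTable:
    rng = _rng(cfg, 2)
    gene_ids = [g.gene_id for g in genes]
    base = np.power(2.0, rng.normal(2.0, 2.0, size=len(genes)))
    active_targets = {e.target_gene for e in elements
                      if e.kind == "active_DRE" and e.target_gene}
    gain_targets = {e.target_gene for e in elements
                    if e.dynamics == "gain" and e.target_gene}
    control = base.copy()
    treated = base.copy()
    for i, gid in enumerate(gene_ids):
        if gid in active_targets:
            control[i] *= cfg.expression_coupling
            treated[i] *= cfg.expression_coupling
        if gid in gain_targets:
            treated[i] *= cfg.expression_coupling
    df = pd.DataFrame({"control": control, "treated": treated}, index=gene_ids)
    return ExpressionTable(df)


def _coverage_categories(expr: ExpressionTable, none_threshold: float = 1.0
                         ) -> dict[str, str]:
    """Control-condition expression categories driving coverage amplitudes.

    Same rank-tertile rule as the analysis side; kept as the generator's own
    few lines so truth is not defined by the code under test.
    """
    vals = expr.rpkm["control"]
    out = {}
    expressed = sorted((float(v), gid) for gid, v in vals.items()
                       if v >= none_threshold)
    for gid, v in vals.items():
        if v < none_threshold:
            out[gid] = "none"
    n = len(expressed)
    q, r = divmod(n, 3)
    bounds = [q + (1 if r >= 1 else 0)]
    bounds.append(bounds[0] + q + (1 if r >= 2 else 0))
    for rank, (_, gid) in enumerate(expressed):
        out[gid] = "low" if rank < bounds[0] else ("medium" if rank < bounds[1] else "high")
    return out


_CAT_FACTOR = {"none": 0.1, "low": 0.6, "medium": 1.2, "high": 2.4}


# ---------------------------------------------------------------------------
# planted peaks and coverage
# ---------------------------------------------------------------------------

def _planted_peaks(cfg: SimulationConfig, genes: list[GeneModel],
                   elements: list[_Element]) -> dict[tuple[str, str], list[Peak]]:
    """Noise-free peak lists per (mark, condition)."""
    peaks: dict[tuple[str, str], list[Peak]] = {
        (m, c): [] for m in MARKS for c in CONDITIONS}
    for e in elements:
        if e.kind == "promoter":
            for cond in CONDITIONS:
                for mark in ("H3K4me3", "H3K27ac"):
                    peaks[(mark, cond)].append(Peak(
                        GenomicInterval(e.scaffold, e.start, e.end),
                        f"{e.element_id}_{mark}", cfg.depth, e.summit - e.start))
        else:
            c = e.summit
            for cond in CONDITIONS:
                peaks[("H3K4me1", cond)].append(Peak(
                    GenomicInterval(e.scaffold, c - 600, c + 600),
                    f"{e.element_id}_me1", cfg.depth, 600))
            if e.kind == "active_DRE":
                # established enhancer: flanking acetylation around the core
                for cond in CONDITIONS:
                    peaks[("H3K27ac", cond)].append(Peak(
                        GenomicInterval(e.scaffold, c - 650, c - 150),
                        f"{e.element_id}_ac_l", cfg.depth, 250))
                    peaks[("H3K27ac", cond)].append(Peak(
                        GenomicInterval(e.scaffold, c + 150, c + 650),
                        f"{e.element_id}_ac_r", cfg.depth, 250))
            elif e.dynamics == "gain":
                # nascent acetylation: single treated-only peak
                peaks[("H3K27ac", "treated")].append(Peak(
                    GenomicInterval(e.scaffold, c - 600, c + 600),
                    f"{e.element_id}_ac_gain", cfg.depth, 600))
    return peaks


def _add_bump(arr: np.ndarray, center: int, sigma: float, amp: float) -> None:
    lo = max(0, int(center - 3 * sigma))
    hi = min(len(arr), int(center + 3 * sigma) + 1)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    arr[lo:hi] += amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def _coverage(cfg: SimulationConfig, lengths: dict[str, int],
              genes: list[GeneModel], elements: list[_Element],
              categories: dict[str, str]) -> dict[tuple[str, str], CoverageTrack]:
    """Poisson-sampled tracks at ``coverage_step`` resolution.

    Expected density: a flat background plus Gaussian bumps — unimodal
    H3K4me3/H3K27ac at promoters (amplitude by expression category),
    bimodal H3K4me1 at promoters and enhancer cores, flanking H3K27ac at
    established active enhancers, and a single treated-amplified bump at
    activated enhancers. Only the activated-enhancer H3K27ac differs
    between conditions.
    """
    rng = _rng(cfg, 3)
    bg = cfg.background_fraction * cfg.depth
    by_gene = {g.gene_id: g for g in genes}
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for mark in MARKS:
        for cond in CONDITIONS:
            values: dict[str, np.ndarray] = {}
            total = 0.0
            for scaf in sorted(lengths):
                lam = np.full(lengths[scaf], bg, dtype=np.float64)
                for g in genes:
                    if g.interval.scaffold != scaf:
                        continue
                    f = _CAT_FACTOR[categories[g.gene_id]]
                    if mark == "H3K4me3":
                        _add_bump(lam, g.tss, 300, cfg.depth * f)
                    elif mark == "H3K27ac":
                        _add_bump(lam, g.tss, 300, 0.8 * cfg.depth * f)
                    else:
                        _add_bump(lam, g.tss - 500, 200, 0.35 * cfg.depth * f)
                        _add_bump(lam, g.tss + 500, 200, 0.35 * cfg.depth * f)
                for e in elements:
                    if e.scaffold != scaf or e.kind == "promoter":
                        continue
                    c = e.summit
                    if mark == "H3K4me1":
                        _add_bump(lam, c - 300, 200, cfg.depth)
                        _add_bump(lam, c + 300, 200, cfg.depth)
                    elif mark == "H3K27ac":
                        if e.kind == "active_DRE":
                            _add_bump(lam, c - 400, 150, cfg.depth)
                            _add_bump(lam, c + 400, 150, cfg.depth)
                        elif e.dynamics == "gain":
                            amp = cfg.depth if cond == "treated" else cfg.depth / cfg.fold_gain
                            _add_bump(lam, c, 250, amp)
                lam_bins = lam.reshape(-1, cfg.coverage_step).sum(axis=1)
                counts = rng.poisson(lam_bins).astype(np.float64)
                values[scaf] = counts / cfg.coverage_step
                total += counts.sum()
            # library size in sequenced tags: per-base coverage integrates
            # READ_LENGTH bases per tag
            tracks[(mark, cond)] = CoverageTrack(
                values, library_size=max(total, 1.0) / READ_LENGTH,
                step=cfg.coverage_step)
    return tracks


# ---------------------------------------------------------------------------
# receptor peaks, sequence and motif planting
# ---------------------------------------------------------------------------

def _ecr_peaks(cfg: SimulationConfig, elements: list[_Element],
               free_blocks: list[tuple[str, int]]):
    """Choose receptor peak hosts and motif-planting flags."""
    rng = _rng(cfg, 4)
    promoters = [e for e in elements if e.kind == "promoter"]
    dres = [e for e in elements if e.kind != "promoter"]
    n_prom = min(cfg.n_ecr_peaks // 4, len(promoters))
    n_dre = min(cfg.n_ecr_peaks // 4, len(dres))
    n_inter = cfg.n_ecr_peaks - n_prom - n_dre
    if n_inter > len(free_blocks):
        raise ValueError(
            f"{n_inter} intergenic receptor peaks do not fit in "
            f"{len(free_blocks)} free blocks; enlarge the genome")
    prom_pick = rng.choice(len(promoters), size=n_prom, replace=False)
    dre_pick = rng.choice(len(dres), size=n_dre, replace=False)
    inter_pick = rng.choice(len(free_blocks), size=n_inter, replace=False)
    hosts: list[tuple[str, str, int, str]] = []   # (host_kind, scaffold, point, host_id)
    for i in sorted(prom_pick):
        e = promoters[i]
        hosts.append((e.kind, e.scaffold, e.summit, e.element_id))
    for i in sorted(dre_pick):
        e = dres[i]
        hosts.append((e.kind, e.scaffold, e.summit, e.element_id))
    for i in sorted(inter_pick):
        scaf, bstart = free_blocks[i]
        hosts.append(("intergenic", scaf, bstart + cfg.block_size // 2, ""))
    planted = rng.random(len(hosts)) < cfg.ecre_plant_fraction
    rows = []
    for k, (host_kind, scaf, point, host_id) in enumerate(hosts):
        rows.append({
            "name": f"ecr{k:04d}", "scaffold": scaf,
            "start": point - 300, "end": point + 300, "summit": point,
            "host_kind": host_kind, "host_element": host_id,
            "motif_planted": bool(planted[k]),
        })
    return pd.DataFrame(rows)


def _match_counts(window: np.ndarray, fwd: np.ndarray, rev: np.ndarray) -> int:
    return max(int((window == fwd).sum()), int((window == rev).sum()))


def _sequence(cfg: SimulationConfig, lengths: dict[str, int],
              ecr_df: pd.DataFrame) -> dict[str, str]:
    """Random genome with motif instances planted inside receptor peaks.

    Near-consensus background matches (>= 11/13 agreement on either strand)
    inside receptor peaks are deterministically disrupted outside the
    planted span, so that in the noise-free limit motif presence in a
    receptor peak is exactly the planting flag.
    """
    rng = _rng(cfg, 5)
    cons = np.array([_CODE[b] for b in ECRE_CONSENSUS], dtype=np.uint8)
    cons_rc = (3 - cons)[::-1]
    w = len(cons)
    arrays = {s: rng.integers(0, 4, size=n, dtype=np.uint8).copy()
              for s, n in sorted(lengths.items())}

    planted_spans: dict[str, list[tuple[int, int]]] = {s: [] for s in arrays}
    for row in ecr_df.itertuples():
        if not row.motif_planted:
            continue
        arr = arrays[row.scaffold]
        offset = int(rng.integers(50, (row.end - row.start) - 50 - w))
        pos = row.start + offset
        instance = cons.copy()
        muts = rng.random(w) < cfg.ecre_mutation_rate
        for j in np.flatnonzero(muts):
            instance[j] = (instance[j] + 1 + rng.integers(0, 3)) % 4
        if rng.integers(0, 2) == 1:
            instance = (3 - instance)[::-1]
        arr[pos:pos + w] = instance
        planted_spans[row.scaffold].append((pos, pos + w))

    # scrub chance near-matches inside receptor peaks
    for row in ecr_df.itertuples():
        arr = arrays[row.scaffold]
        spans = [sp for sp in planted_spans[row.scaffold]
                 if sp[0] < row.end and sp[1] > row.start]
        for _ in range(25):
            dirty = False
            for off in range(row.start, row.end - w + 1):
                win = arr[off:off + w]
                if _match_counts(win, cons, cons_rc) < w - 2:
                    continue
                free = [p for p in range(off, off + w)
                        if not any(s <= p < e for s, e in spans)]
                if not free:
                    continue   # the planted instance itself
                p = free[len(free) // 2]
                arr[p] = (arr[p] + 1) % 4
                dirty = True
            if not dirty:
                break
    return {s: _LUT[a].tobytes().decode("ascii") for s, a in arrays.items()}


# ---------------------------------------------------------------------------
# corruption
# ---------------------------------------------------------------------------

def _corrupt(cfg: SimulationConfig, peak_lists: dict[tuple[str, str], list[Peak]],
             ecr_planted: list[Peak],
             lengths: dict[str, int]) -> tuple[dict, list[Peak]]:
    """Summit jitter, dropouts and decoy peaks on every observed list."""
    rng = _rng(cfg, 6)
    scaffolds = sorted(lengths)

    def corrupt_one(peaks: list[Peak], tag: str) -> list[Peak]:
        out: list[Peak] = []
        n = len(peaks)
        jitter = rng.normal(0.0, cfg.summit_jitter_sd, size=n) \
            if cfg.summit_jitter_sd > 0 else np.zeros(n)
        drop = rng.random(n) < cfg.miss_rate
        for i, p in enumerate(peaks):
            if drop[i]:
                continue
            off = p.summit_offset if p.summit_offset is not None else len(p.interval) // 2
            off = int(np.clip(round(off + jitter[i]), 0, len(p.interval) - 1))
            out.append(Peak(p.interval, p.name, p.signal, off))
        n_false = rng.binomial(n, cfg.false_peak_rate) if n else 0
        for k in range(n_false):
            scaf = scaffolds[rng.integers(0, len(scaffolds))]
            width = int(rng.integers(400, 1201))
            start = int(rng.integers(0, lengths[scaf] - width))
            out.append(Peak(GenomicInterval(scaf, start, start + width),
                            f"decoy_{tag}_{k:03d}",
                            round(float(rng.uniform(1, 5)), 3), width // 2))
        out.sort(key=lambda p: (p.interval.scaffold, p.interval.start, p.name))
        return out

    observed = {key: corrupt_one(plist, f"{key[0]}_{key[1]}")
                for key, plist in sorted(peak_lists.items())}
    ecr_observed = corrupt_one(ecr_planted, "EcR_treated")
    return observed, ecr_observed


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir: str | os.PathLike | None = None,
             with_tracks: bool = True, with_sequence: bool = True
             ) -> SimulatedDataset:
    """Generate a complete labeled dataset; optionally write it to disk.

    ``with_tracks``/``with_sequence`` skip the expensive coverage and
    genome-sequence stages for callers that only need layout + expression;
    the remaining stages are unaffected (each stage has its own RNG stream).
    """
    lengths, genes, elements, _, free_blocks = _layout(config)
    expr = _expression(config, genes, elements)
    categories = _coverage_categories(expr)
    ecr_df = _ecr_peaks(config, elements, free_blocks)

    motif_on_element = dict(
        zip(ecr_df["host_element"], ecr_df["motif_planted"]))
    truth_elements = pd.DataFrame([{
        "element_id": e.element_id, "kind": e.kind, "scaffold": e.scaffold,
        "start": e.start, "end": e.end, "summit": e.summit,
        "dynamics": e.dynamics, "target_gene": e.target_gene,
        "tss_distance": e.tss_distance,
        "motif_planted": bool(motif_on_element.get(e.element_id, False)),
    } for e in elements])
    truth = TruthTable(truth_elements, ecr_df)

    planted = _planted_peaks(config, genes, elements)
    ecr_planted = [
        Peak(GenomicInterval(r.scaffold, r.start, r.end), r.name, config.depth,
             r.summit - r.start)
        for r in ecr_df.itertuples()]

    tracks = _coverage(config, lengths, genes, elements, categories) \
        if with_tracks else {}
    genome = _sequence(config, lengths, ecr_df) if with_sequence else {}
    observed, ecr_observed = _corrupt(config, planted, ecr_planted, lengths)

    ds = SimulatedDataset(config, lengths, genes, observed, ecr_observed,
                          tracks, genome, expr, truth, ecre_pwm())
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SimulatedDataset, outdir: str | os.PathLike) -> None:
    """Write every artifact in the plain-text formats the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_scaffold_lengths(ds.scaffold_lengths, out / "scaffolds.tsv")
    dio.write_gene_models(ds.genes, out / "genes.gff3")
    if ds.genome:
        dio.write_fasta(ds.genome, out / "genome.fa")
    for (mark, cond), plist in sorted(ds.peaks.items()):
        dio.write_peaks(plist, out / f"{mark.lower()}_{cond}.narrowPeak")
    dio.write_peaks(ds.ecr_peaks, out / "ecr_treated.narrowPeak")
    for (mark, cond), track in sorted(ds.tracks.items()):
        dio.write_coverage(track, out / f"{mark.lower()}_{cond}.bedGraph")
    if ds.expression is not None:
        dio.write_expression(ds.expression, out / "expression.tsv")
    dio.write_pwm(ds.pwm, out / "ecre_motif.jaspar", counts_scale=100.0)
    if ds.truth is not None:
        ds.truth.elements.to_csv(out / "truth_elements.tsv", sep="\t", index=False)
        ds.truth.ecr_peaks.to_csv(out / "truth_ecr.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

#: predicted (kind, active) -> truth label
_PRED_LABEL = {("promoter", True): "promoter", ("promoter", False): "promoter",
               ("DRE", True): "active_DRE", ("DRE", False): "poised_DRE"}


@dataclass
class RecoveryScore:
    precision: float | None
    recall: float | None
    n_truth: int
    n_predicted: int
    unmatched_truth: list[str]
    unmatched_predicted: list[str]


def truth_compare(predicted_elements, truth: TruthTable,
                  match_distance: int = 500) -> dict[str, RecoveryScore]:
    """Precision/recall of element recovery per planted kind.

    A predicted element matches a planted one iff their summits lie within
    ``match_distance`` bp on the same scaffold and the labels agree
    (predicted promoters vs planted promoters; predicted active/inactive
    DREs vs planted active/poised DREs). Matching is set-based: a predicted
    element counts as correct if any same-label planted element is near,
    and a planted element as recovered if any same-label prediction is.
    """
    truth_by_label: dict[str, dict[str, list]] = {}
    for row in truth.elements.itertuples():
        d = truth_by_label.setdefault(row.kind, {})
        d.setdefault(row.scaffold, []).append((row.summit, row.element_id))
    pred_by_label: dict[str, list] = {}
    for e in predicted_elements:
        label = _PRED_LABEL[(e.kind, e.active)]
        pred_by_label.setdefault(label, []).append(e)

    out: dict[str, RecoveryScore] = {}
    labels = sorted(set(truth_by_label) | set(pred_by_label))
    for label in labels:
        t_sc = {s: np.array(sorted(p for p, _ in pairs))
                for s, pairs in truth_by_label.get(label, {}).items()}
        preds = pred_by_label.get(label, [])
        p_sc: dict[str, np.ndarray] = {}
        for e in preds:
            p_sc.setdefault(e.interval.scaffold, []).append(e.summit)
        p_sc = {s: np.array(sorted(v)) for s, v in p_sc.items()}

        def near(pos_map, scaf, point):
            arr = pos_map.get(scaf)
            if arr is None or len(arr) == 0:
                return False
            i = int(np.searchsorted(arr, point))
            for j in (i - 1, i):
                if 0 <= j < len(arr) and abs(int(arr[j]) - point) <= match_distance:
                    return True
            return False

        unmatched_pred = [e.source_peak.name for e in preds
                          if not near(t_sc, e.interval.scaffold, e.summit)]
        truth_rows = truth_by_label.get(label, {})
        n_truth = sum(len(v) for v in truth_rows.values())
        unmatched_truth = [eid for scaf, pairs in truth_rows.items()
                           for pos, eid in pairs if not near(p_sc, scaf, pos)]
        n_pred = len(preds)
        precision = None if n_pred == 0 else 1 - len(unmatched_pred) / n_pred
        recall = None if n_truth == 0 else 1 - len(unmatched_truth) / n_truth
        out[label] = RecoveryScore(precision, recall, n_truth, n_pred,
                                   unmatched_truth, unmatched_pred)
    return out


def dynamics_recovery(calls, truth: TruthTable, match_distance: int = 500
                      ) -> dict[str, dict[str, float | int]]:
    """Score fold-classification against planted dynamics labels.

    Each planted DRE is matched to the call whose region is nearest its
    summit (within ``match_distance`` of the region span). Returns, per
    planted label, the matched count and the fraction classified
    "increased" — the sensitivity for "gain" rows, the false-positive rate
    for "stable" rows.
    """
    by_scaf: dict[str, list] = {}
    for call in calls:
        by_scaf.setdefault(call.region.scaffold, []).append(call)
    results: dict[str, dict[str, float | int]] = {}
    for label in ("gain", "stable"):
        rows = truth.elements[(truth.elements["kind"] != "promoter")
                              & (truth.elements["dynamics"] == label)]
        n_matched = n_increased = 0
        for row in rows.itertuples():
            best = None
            for call in by_scaf.get(row.scaffold, []):
                if call.region.start - match_distance <= row.summit < call.region.end + match_distance:
                    d = abs((call.region.start + call.region.end) // 2 - row.summit)
                    if best is None or d < best[0]:
                        best = (d, call)
            if best is None:
                continue
            n_matched += 1
            if best[1].klass == "increased":
                n_increased += 1
        results[label] = {
            "n_planted": len(rows), "n_matched": n_matched,
            "increased_fraction": (n_increased / n_matched) if n_matched else float("nan"),
        }
    return results


def motif_recovery(per_peak_table: pd.DataFrame, truth: TruthTable
                   ) -> RecoveryScore:
    """Precision/recall of motif-bearing receptor-peak detection.

    Observed peaks are matched to planted ones by name; decoys (absent from
    the truth table) count as planted=False. Scored over observed peaks.
    """
    truth_flags = dict(zip(truth.ecr_peaks["name"], truth.ecr_peaks["motif_planted"]))
    tp = fp = fn = 0
    missed, spurious = [], []
    for row in per_peak_table.itertuples():
        planted = bool(truth_flags.get(row.peak, False))
        detected = bool(row.has_motif)
        if planted and detected:
            tp += 1
        elif detected:
            fp += 1
            spurious.append(row.peak)
        elif planted:
            fn += 1
            missed.append(row.peak)
    precision = tp / (tp + fp) if (tp + fp) else None
    recall = tp / (tp + fn) if (tp + fn) else None
    return RecoveryScore(precision, recall, tp + fn, tp + fp, missed, spurious)
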