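"""Log-odds PWM scanning of peak sequences.

Both strands are scanned; a window is a hit when its log2-odds score
reaches ``threshold_fraction`` of the way from the matrix's minimum to its
maximum achievable score. Windows containing N are skipped. Used to count
peaks containing at least one occurrence of a supplied motif (e.g. the
EcR/USP ecdysone response element).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import BASE_INDEX, BASES, PWM, Peak

DEFAULT_THRESHOLD_FRACTION = 0.80

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifHit:
    """One scored motif occurrence inside a scanned sequence."""

    peak_name: str
    offset: int       # bp from sequence start (left end of the window)
    strand: str       # "+" | "-"
    score: float      # log2 odds vs background


def log_odds_matrix(pwm: PWM) -> np.ndarray:
    """cell(b, j) = log2(P(b at j) / background(b)).

    The PWM must already be probability-normalized (see
    :meth:`dremap.model.PWM.normalized`); zero probabilities would produce
    -inf cells and are rejected.
    """
    if np.any(pwm.matrix <= 0):
        raise ValueError("PWM has zero cells; normalize with a pseudocount first")
    return np.log2(pwm.matrix / pwm.background[:, None])


def score_range(lom: np.ndarray) -> tuple[float, float]:
    """(min, max) achievable window scores: per-column extreme sums."""
    return float(lom.min(axis=0).sum()), float(lom.max(axis=0).sum())


def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N) -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = idx
    return out


def scan_sequence(seq: str, lom: np.ndarray,
                  threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
                  peak_name: str = "") -> list[MotifHit]:
    """All hits of a log-odds matrix in a sequence, both strands.

    The reverse strand is scanned by reversing and complementing the matrix
    (rows and columns flipped), so "-" hit offsets stay in the forward
    coordinate frame. Hits are returned in coordinate order; overlapping
    hits are all reported.
    """
    if not 0 <= threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in [0, 1]")
    w = lom.shape[1]
    n = len(seq)
    if n < w:
        return []
    lo, hi = score_range(lom)
    # tiny slack so summation order cannot drop an exact-threshold window
    threshold = lo + threshold_fraction * (hi - lo) - 1e-9
    enc = _encode(seq.upper())
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)  # (n-w+1, w)
    valid = ~(windows < 0).any(axis=1)
    cols = np.arange(w)
    # complement = row flip (A<->T, C<->G under ACGT order), reverse = col flip
    rc_lom = lom[::-1, ::-1]
    hits: list[MotifHit] = []
    if valid.any():
        safe = np.where(windows < 0, 0, windows)
        fwd = lom[safe, cols].sum(axis=1)
        rev = rc_lom[safe, cols].sum(axis=1)
        for off in np.flatnonzero(valid):
            if fwd[off] >= threshold:
                hits.append(MotifHit(peak_name, int(off), "+", float(fwd[off])))
            if rev[off] >= threshold:
                hits.append(MotifHit(peak_name, int(off), "-", float(rev[off])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def peaks_with_motif(peaks: Sequence[Peak], genome: Mapping[str, str], pwm: PWM,
                     threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
                     ) -> tuple[int, float | None, pd.DataFrame]:
    """Count peaks whose sequence contains at least one motif hit.

    Returns (count, count/len(peaks), per-peak table with the best hit).
    The fraction is None for an empty peak list. Peaks on scaffolds missing
    from the genome are an error naming the scaffold.
    """
    lom = log_odds_matrix(pwm)
    rows = []
    count = 0
    for p in peaks:
        iv = p.interval
        if iv.scaffold not in genome:
            raise KeyError(f"scaffold {iv.scaffold!r} missing from genome FASTA")
        seq = genome[iv.scaffold][iv.start:iv.end]
        hits = scan_sequence(seq, lom, threshold_fraction, p.name)
        best = max(hits, key=lambda h: h.score) if hits else None
        if hits:
            count += 1
        rows.append({
            "peak": p.name, "scaffold": iv.scaffold, "start": iv.start,
            "end": iv.end, "n_hits": len(hits),
            "best_score": best.score if best else np.nan,
            "best_offset": best.offset if best else -1,
            "best_strand": best.strand if best else ".",
            "has_motif": int(bool(hits)),
        })
    fraction = count / len(peaks) if peaks else None
    return count, fraction, pd.DataFrame(rows)


def genome_background(genome: Mapping[str, str]) -> np.ndarray:
    """Mononucleotide background frequencies of a genome (N excluded)."""
    counts = np.zeros(4, dtype=np.int64)
    for seq in genome.values():
        enc = _encode(seq)
        counts += np.bincount(enc[enc >= 0], minlength=4)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return counts / total
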