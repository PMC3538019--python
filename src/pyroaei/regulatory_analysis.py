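"""Promoter-sequence analysis: CpG islands, motif scanning, SNP co-localization.

CpG islands follow the classic Gardiner-Garden/Frommer criteria (length
>= 200 bp, G+C >= 0.5, CpG observed/expected >= 0.6): a fixed-length window
slides at 1 bp steps, qualifying windows are merged, and each merged
interval is trimmed to the maximal sub-interval that still satisfies all
three criteria.  N bases break islands.  The obs/exp ratio is
``n_CpG * L / (n_C * n_G)`` computed from the interval's own counts, and is
defined as 0 when ``n_C * n_G`` is 0.

Motif scanning is a plain log-odds position-weight-matrix scanner against a
uniform background with a 0.25 pseudocount per cell; hits are thresholded
on the min-max normalised score fraction, and minus-strand hits are
reported in plus-strand coordinates.

TSS-relative positions are 1-based with no position 0: -1 is the base
immediately 5' of the transcription start.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._sequence import base_indices, revcomp
from .errors import ValidationError
from .io_formats import Pwm

logger = logging.getLogger("pyroaei")


# ---------------------------------------------------------------------------
# CpG statistics and islands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpGStats:
    n_cpg: int
    n_c: int
    n_g: int
    gc_fraction: float
    obs_exp: float


def cpg_stats(seq: str) -> CpGStats:
    """CpG dinucleotide statistics of a sequence (overlap-counted).

    GpC is not CpG; obs/exp is ``n_cpg * L / (n_C * n_G)`` and 0 when the
    sequence has no C or no G.
    """
    if not seq:
        raise ValidationError("cpg_stats requires a non-empty sequence")
    n = len(seq)
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = sum(1 for i in range(n - 1) if seq[i] == "C" and seq[i + 1] == "G")
    denom = n_c * n_g
    return CpGStats(
        n_cpg=n_cpg,
        n_c=n_c,
        n_g=n_g,
        gc_fraction=(n_c + n_g) / n,
        obs_exp=(n_cpg * n / denom) if denom else 0.0,
    )


@dataclass(frozen=True)
class CpGIsland:
    """One detected island; coordinates 0-based half-open on the input."""

    start: int
    end: int
    n_cpg: int
    gc_fraction: float
    obs_exp: float

    @property
    def length(self) -> int:
        return self.end - self.start


def island_criteria_met(
    seq: str, start: int, end: int, min_len: int = 200, min_gc: float = 0.5, min_oe: float = 0.6
) -> bool:
    """Independent verifier: does [start, end) satisfy all three criteria?"""
    if end - start < min_len:
        return False
    st = cpg_stats(seq[start:end])
    return st.gc_fraction >= min_gc and st.obs_exp >= min_oe


def find_cpg_islands(
    seq: str,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Sliding-window CpG island detection with merge and trim.

    Windows of ``min_len`` slide at 1 bp; windows meeting all criteria are
    flagged; overlapping or adjacent flagged windows merge; each merged
    interval is trimmed to its maximal (longest, then leftmost) sub-interval
    that satisfies all three criteria, which always exists because at least
    one window did.  Characters other than ACGTN raise; N terminates
    windows, so no island spans an N run.
    """
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValidationError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    islands: list[CpGIsland] = []
    offset = 0
    for run in seq.split("N"):
        if len(run) >= min_len:
            islands.extend(
                CpGIsland(
                    start=s + offset, end=e + offset,
                    n_cpg=st.n_cpg, gc_fraction=st.gc_fraction, obs_exp=st.obs_exp,
                )
                for (s, e, st) in _islands_in_run(run, min_len, min_gc, min_oe)
            )
        offset += len(run) + 1  # the N itself
    logger.info("find_cpg_islands: %d islands in %d bp", len(islands), len(seq))
    return islands


def _prefix_counts(run: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(run.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(len(run), dtype=np.int64)
    if len(run) > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(is_cg)]),
        np.concatenate([zero, np.cumsum(is_c + is_g)]),
    )


def _interval_ok(pc, pg, pcg, pgc, s, e, min_gc, min_oe):
    L = e - s
    n_c = pc[e] - pc[s]
    n_g = pg[e] - pg[s]
    # CpG pairs fully inside [s, e): starts in [s, e-1)
    n_cpg = pcg[e - 1] - pcg[s] if e - 1 > s else 0
    gc = (pgc[e] - pgc[s]) / L
    denom = n_c * n_g
    oe = (n_cpg * L / denom) if denom else 0.0
    return gc >= min_gc and oe >= min_oe


def _islands_in_run(run: str, min_len: int, min_gc: float, min_oe: float):
    n = len(run)
    pc, pg, pcg, pgc = _prefix_counts(run)
    starts = np.arange(n - min_len + 1)
    ends = starts + min_len
    n_c = pc[ends] - pc[starts]
    n_g = pg[ends] - pg[starts]
    n_cpg = pcg[ends - 1] - pcg[starts]
    gc = (pgc[ends] - pgc[starts]) / min_len
    denom = n_c * n_g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cpg * min_len / np.where(denom > 0, denom, 1), 0.0)
    flagged = (gc >= min_gc) & (oe >= min_oe)
    out = []
    for ms, me in _merge_flagged(starts[flagged], min_len):
        trimmed = _trim_to_criteria(pc, pg, pcg, pgc, ms, me, min_len, min_gc, min_oe)
        if trimmed is not None:
            s, e = trimmed
            st = cpg_stats(run[s:e])
            assert st.gc_fraction >= min_gc and st.obs_exp >= min_oe  # re-verify post-merge
            out.append((s, e, st))
    return out


def _merge_flagged(flag_starts: np.ndarray, window: int) -> list[tuple[int, int]]:
    """Union of flagged windows; overlapping or adjacent windows merge."""
    merged: list[tuple[int, int]] = []
    for s in flag_starts:
        s, e = int(s), int(s) + window
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _trim_to_criteria(pc, pg, pcg, pgc, ms, me, min_len, min_gc, min_oe):
    """Longest (then leftmost) sub-interval of [ms, me) meeting all criteria."""
    m = me - ms
    for L in range(m, min_len - 1, -1):
        for s in range(ms, me - L + 1):
            if _interval_ok(pc, pg, pcg, pgc, s, s + L, min_gc, min_oe):
                return (s, s + L)
    return None


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    pwm_id: str
    start: int  # plus-strand, 0-based
    strand: str
    score: float  # log-odds, bits
    score_fraction: float  # min-max normalised, in [0, 1]
    length: int  # motif length, so [start, start+length) is the footprint


def _log_odds(pwm: Pwm, pseudocount: float = 0.25) -> np.ndarray:
    counts = pwm.counts + pseudocount
    probs = counts / counts.sum(axis=0, keepdims=True)
    return np.log2(probs / 0.25)


def scan_pwm(
    seq: str,
    pwm: Pwm,
    min_score_fraction: float = 0.8,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All PWM hits with min-max normalised score >= ``min_score_fraction``.

    Log-odds scoring in bits against a uniform background with additive
    pseudocount 0.25 per cell.  ``score_fraction`` rescales the score
    between the motif's minimum and maximum possible scores, so a threshold
    of 0 accepts every position and 1.0 only the optimal word.  Positions
    containing non-ACGT characters score the column minimum.  Minus-strand
    hits carry plus-strand start coordinates.
    """
    if len(pwm) == 0:
        raise ValidationError("zero-column PWM")
    if len(pwm) > len(seq):
        return []
    lom = _log_odds(pwm)
    max_score = lom.max(axis=0).sum()
    min_score = lom.min(axis=0).sum()
    span = max_score - min_score
    hits: list[MotifHit] = []
    seq = seq.upper()
    n, m = len(seq), len(pwm)

    def _scan(s: str, strand: str):
        idx = base_indices(s)
        col_min = lom.min(axis=0)
        n_pos = len(s) - m + 1
        scores = np.zeros(n_pos)
        for j in range(m):
            col = idx[j:j + n_pos]
            vals = np.where(col >= 0, lom[np.clip(col, 0, 3), j], col_min[j])
            scores += vals
        frac = (scores - min_score) / span if span > 0 else np.ones(n_pos)
        for pos in np.flatnonzero(frac >= min_score_fraction):
            start = int(pos) if strand == "+" else n - m - int(pos)
            hits.append(MotifHit(pwm.id, start, strand, float(scores[pos]), float(frac[pos]), m))

    _scan(seq, "+")
    if both_strands:
        _scan(revcomp(seq), "-")
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# SNP annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    position: int  # TSS-relative, 1-based, negative upstream, no 0
    alleles: tuple[str, str]
    overlapping_hits: tuple[MotifHit, ...]
    cpg_effect: str  # creates | destroys | shifts | none
    affected_positions: tuple[int, ...]  # TSS-relative starts of CG dinucleotides involved


def tss_relative(index: int, tss_index: int) -> int:
    """0-based sequence index -> TSS-relative position (no position 0)."""
    return index - tss_index + 1 if index >= tss_index else index - tss_index


def tss_to_index(position: int, tss_index: int) -> int:
    """TSS-relative position -> 0-based sequence index."""
    if position == 0:
        raise ValidationError("TSS-relative coordinates have no position 0")
    return tss_index + position - 1 if position > 0 else tss_index + position


def _cg_starts(window: str, window_start: int) -> set[int]:
    return {
        window_start + i
        for i in range(len(window) - 1)
        if window[i] == "C" and window[i + 1] == "G"
    }


def classify_cpg_effect(seq: str, index: int, ref: str, alt: str) -> tuple[str, set[int], set[int]]:
    """Compare CG dinucleotides in the two allele sequences around a SNP.

    Looks at the +-1 bp window; returns (effect, ref CG starts, alt CG
    starts) with starts as 0-based sequence indices.  'shifts' means both
    alleles carry the same number of CGs but at different offsets — e.g. a
    C/G SNP between an upstream C and a downstream G moves the dinucleotide
    by one base.
    """
    lo = max(0, index - 1)
    hi = min(len(seq), index + 2)
    ref_window = seq[lo:index] + ref + seq[index + 1:hi]
    alt_window = seq[lo:index] + alt + seq[index + 1:hi]
    ref_cg = _cg_starts(ref_window, lo)
    alt_cg = _cg_starts(alt_window, lo)
    if ref_cg == alt_cg:
        effect = "none"
    elif len(alt_cg) > len(ref_cg):
        effect = "creates"
    elif len(alt_cg) < len(ref_cg):
        effect = "destroys"
    else:
        effect = "shifts"
    return effect, ref_cg, alt_cg


def annotate_snps(
    seq: str,
    tss_index: int,
    snps: Sequence[tuple[str, int, str, str]],
    hits: Sequence[MotifHit],
) -> list[SnpAnnotation]:
    """Annotate SNPs with overlapping motif hits and CpG-dinucleotide effects.

    ``snps`` rows are (snp_id, TSS-relative position, ref, alt); ``tss_index``
    is the 0-based index of the +1 base in ``seq``.  A hit overlaps a SNP iff
    the SNP index lies in [hit.start, hit.start + hit.length).  The ref
    allele must match the sequence; a mismatch raises naming the position.
    """
    seq = seq.upper()
    out = []
    for snp_id, position, ref, alt in snps:
        index = tss_to_index(position, tss_index)
        if not 0 <= index < len(seq):
            raise ValidationError(f"SNP {snp_id} position {position} outside sequence")
        if seq[index] != ref.upper():
            raise ValidationError(
                f"SNP {snp_id}: ref allele {ref} disagrees with sequence base "
                f"{seq[index]} at TSS-relative position {position}"
            )
        overlapping = tuple(
            h for h in hits
            if h.start <= index < h.start + h.length
        )
        effect, ref_cg, alt_cg = classify_cpg_effect(seq, index, ref.upper(), alt.upper())
        affected = tuple(sorted(tss_relative(i, tss_index) for i in ref_cg | alt_cg))
        out.append(SnpAnnotation(
            snp_id=snp_id,
            position=position,
            alleles=(ref.upper(), alt.upper()),
            overlapping_hits=overlapping,
            cpg_effect=effect,
            affected_positions=affected,
        ))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report_regulatory(
    islands: Sequence[CpGIsland],
    annotations: Sequence[SnpAnnotation],
    chrom: str = "chrP",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two report tables: islands (BED-style + stats) and SNP annotations.

    Island coordinates are 0-based half-open (BED convention); SNP positions
    are TSS-relative 1-based.  Both tables keep their headers when empty.
    """
    island_df = pd.DataFrame(
        [
            {
                "chrom": chrom,
                "start": isl.start,
                "end": isl.end,
                "length": isl.length,
                "n_cpg": isl.n_cpg,
                "gc_fraction": isl.gc_fraction,
                "obs_exp": isl.obs_exp,
            }
            for isl in islands
        ],
        columns=["chrom", "start", "end", "length", "n_cpg", "gc_fraction", "obs_exp"],
    )
    snp_df = pd.DataFrame(
        [
            {
                "snp_id": a.snp_id,
                "tss_position": a.position,
                "ref": a.alleles[0],
                "alt": a.alleles[1],
                "motifs": ";".join(sorted({h.pwm_id for h in a.overlapping_hits})),
                "n_motif_hits": len(a.overlapping_hits),
                "cpg_effect": a.cpg_effect,
                "affected_cg_positions": ";".join(str(p) for p in a.affected_positions),
            }
            for a in annotations
        ],
        columns=[
            "snp_id", "tss_position", "ref", "alt", "motifs",
            "n_motif_hits", "cpg_effect", "affected_cg_positions",
        ],
    )
    return island_df, snp_df


def islands_to_bed(islands: Sequence[CpGIsland], chrom: str = "chrP") -> list[tuple]:
    return [
        (chrom, isl.start, isl.end, f"CpG_{i + 1}", isl.n_cpg)
        for i, isl in enumerate(islands)
    ]
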