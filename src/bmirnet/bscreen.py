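"""Screening for B-chromosome copies of miRNA loci.

Three complementary strategies around the genomic coverage-ratio signal: a
region duplicated on the B chromosome shows ~2x read depth in the B+ library
relative to the B- library (e.g. 60x B- vs 120x B+ after library-size
normalization). Strategy 1 windows the depth tracks, normalizes by per-library
median depth, and calls "B-blocks" as runs of elevated-ratio windows.
Strategy 2 rescues reads that fail to align to the reference assembly by
aligning them to the B+ assembly and flags candidate loci supported only by
B+ samples. The qPCR gene-dose-ratio calculator (2^-ddCq against a reference
gene) validates candidate loci.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PreMiRNA, _norm, revcomp

log = logging.getLogger(__name__)


@dataclass
class CoverageWindow:
    contig: str
    start: int
    end: int
    depth_bminus: float
    depth_bplus: float
    norm_ratio: float | None = None  # None = undefined (zero B- depth)


@dataclass
class BBlock:
    contig: str
    start: int
    end: int
    mean_ratio: float
    n_windows: int


@dataclass
class GDRResult:
    target_gene: str
    delta_delta_cq: float
    dose_ratio: float
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Strategy 1: coverage-ratio block calling
# ---------------------------------------------------------------------------

def window_coverage(
    track_bminus: pd.DataFrame,
    track_bplus: pd.DataFrame,
    window: int = 1000,
) -> list[CoverageWindow]:
    """Mean depth per fixed-size window for both libraries.

    Tracks are DataFrames with columns (contig, start, end, depth), 0-based
    half-open, either per-base or pre-windowed; intervals are averaged into
    ``window``-sized bins weighted by overlap length. Terminal partial
    windows are retained with their true length. Both tracks must cover the
    same contigs.
    """
    contigs_m = set(track_bminus["contig"])
    contigs_p = set(track_bplus["contig"])
    if contigs_m != contigs_p:
        only = sorted(contigs_m.symmetric_difference(contigs_p))
        raise ValueError(f"contigs present in only one track: {only}")
    out: list[CoverageWindow] = []
    for contig in sorted(contigs_m):
        tm = track_bminus[track_bminus["contig"] == contig]
        tp = track_bplus[track_bplus["contig"] == contig]
        length = int(max(tm["end"].max(), tp["end"].max()))
        means_m = _window_means(tm, length, window)
        means_p = _window_means(tp, length, window)
        for wi in range(len(means_m)):
            ws = wi * window
            we = min(ws + window, length)
            out.append(CoverageWindow(contig, ws, we, means_m[wi], means_p[wi]))
    return out


def _window_means(track: pd.DataFrame, length: int, window: int) -> np.ndarray:
    """Overlap-weighted mean depth per window from arbitrary intervals."""
    n_win = math.ceil(length / window)
    total = np.zeros(n_win)
    covered = np.zeros(n_win)
    starts = track["start"].to_numpy()
    ends = track["end"].to_numpy()
    depths = track["depth"].to_numpy(dtype=float)
    for s, e, d in zip(starts, ends, depths):
        for wi in range(s // window, min((e - 1) // window + 1, n_win)):
            lo, hi = max(s, wi * window), min(e, (wi + 1) * window)
            if hi > lo:
                total[wi] += d * (hi - lo)
                covered[wi] += hi - lo
    with np.errstate(invalid="ignore"):
        return np.where(covered > 0, total / np.maximum(covered, 1), 0.0)


def normalize_and_ratio(windows: Sequence[CoverageWindow]) -> list[CoverageWindow]:
    """Library-size-normalized B+/B- depth ratio per window.

    Depths are scaled by each library's genome-wide median so that a global
    sequencing-depth difference cancels:
    ratio = (d+ / median+) / (d- / median-). Windows with zero B- depth get
    an undefined ratio (None) and are excluded from block calling.
    """
    med_m = float(np.median([w.depth_bminus for w in windows]))
    med_p = float(np.median([w.depth_bplus for w in windows]))
    if med_m <= 0 or med_p <= 0:
        raise ValueError("genome-wide median depth must be positive in both libraries")
    out = []
    for w in windows:
        if w.depth_bminus <= 0:
            ratio = None
        else:
            ratio = (w.depth_bplus / med_p) / (w.depth_bminus / med_m)
        out.append(CoverageWindow(w.contig, w.start, w.end, w.depth_bminus, w.depth_bplus, ratio))
    return out


def call_bblocks(
    windows: Sequence[CoverageWindow],
    ratio_min: float = 1.5,
    min_windows: int = 3,
    merge_gap: int = 1,
) -> list[BBlock]:
    """Call B-blocks as runs of elevated-ratio windows.

    A block is a maximal run of windows with norm_ratio >= ratio_min on one
    contig, tolerating gaps of up to ``merge_gap`` consecutive sub-threshold
    (or undefined) windows; runs supported by fewer than ``min_windows``
    elevated windows are discarded. mean_ratio averages the elevated member
    windows only. Output intervals are disjoint and sorted.
    """
    by_contig: dict[str, list[CoverageWindow]] = {}
    for w in windows:
        by_contig.setdefault(w.contig, []).append(w)
    blocks: list[BBlock] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda w: w.start)
        run: list[CoverageWindow] = []
        gap = 0
        for w in ordered:
            elevated = w.norm_ratio is not None and w.norm_ratio >= ratio_min
            if elevated:
                run.append(w)
                gap = 0
            elif run:
                gap += 1
                if gap > merge_gap:
                    _flush_run(run, contig, min_windows, blocks)
                    run, gap = [], 0
        _flush_run(run, contig, min_windows, blocks)
    return blocks


def _flush_run(
    run: list[CoverageWindow], contig: str, min_windows: int, blocks: list[BBlock]
) -> None:
    if len(run) >= min_windows:
        ratios = [w.norm_ratio for w in run]
        blocks.append(
            BBlock(contig, run[0].start, run[-1].end, float(np.mean(ratios)), len(run))
        )
    run.clear()


def intersect_annotations(
    blocks: Sequence[BBlock], precursors: Sequence[PreMiRNA]
) -> list[tuple[PreMiRNA, BBlock, float]]:
    """Precursors overlapping any B-block by >= 1 base.

    Returns (precursor, block, overlap fraction of the precursor). An empty
    result is a valid, reportable outcome: no miRNA gene inside a duplicated
    region.
    """
    out = []
    for p in precursors:
        for b in blocks:
            if p.contig != b.contig:
                continue
            overlap = min(p.end, b.end) - max(p.start, b.start)
            if overlap >= 1:
                out.append((p, b, overlap / (p.end - p.start)))
    return out


def write_blocks_bed(blocks: Sequence[BBlock], path) -> None:
    with open(path, "w") as fh:
        for i, b in enumerate(blocks):
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\tbblock_{i}\t{b.mean_ratio:.4f}\n")


# ---------------------------------------------------------------------------
# Strategy 2: unaligned-read rescue against the B+ assembly
# ---------------------------------------------------------------------------

@dataclass
class RescueCandidate:
    contig: str
    start: int
    end: int
    n_reads: int
    samples: frozenset[str]
    bplus_exclusive: bool


def _align_substring(read: str, references: Mapping[str, str], max_mismatches: int):
    """First (contig, position) placement of a short read with <= k mismatches.

    A plain sliding-window substring search over both strands; adequate for
    17-27-nt reads against small references, with no external aligner.
    """
    for contig in sorted(references):
        ref = _norm(references[contig])
        for query in (read, revcomp(read)):
            n = len(query)
            if n > len(ref):
                continue
            if max_mismatches == 0:
                i = ref.find(query)
                if i != -1:
                    return contig, i
                continue
            for i in range(len(ref) - n + 1):
                mm = 0
                for a, b in zip(query, ref[i : i + n]):
                    if a != b:
                        mm += 1
                        if mm > max_mismatches:
                            break
                if mm <= max_mismatches:
                    return contig, i
    return None


def rescue_unaligned(
    reads: Iterable[tuple[str, str, str]],
    reference_a: Mapping[str, str],
    reference_bplus: Mapping[str, str],
    max_mismatches: int = 1,
    merge_distance: int = 100,
) -> list[RescueCandidate]:
    """Rescue reads unaligned to the reference assembly via the B+ assembly.

    ``reads`` yields (read_id, sequence, sample_group) with sample_group in
    {"Bminus", "Bplus"}. Reads placing nowhere on ``reference_a`` at
    <= max_mismatches are aligned to ``reference_bplus``; placements within
    ``merge_distance`` bases on one contig group into a candidate region. A
    region is B+-exclusive iff every supporting read comes from a B+ sample.
    """
    hits: list[tuple[str, int, int, str]] = []
    for rid, seq, group in reads:
        seq = _norm(seq)
        if _align_substring(seq, reference_a, max_mismatches) is not None:
            continue
        placed = _align_substring(seq, reference_bplus, max_mismatches)
        if placed is None:
            continue
        contig, pos = placed
        hits.append((contig, pos, pos + len(seq), group))
    hits.sort()
    candidates: list[RescueCandidate] = []
    cur: list[tuple[str, int, int, str]] = []
    for h in hits:
        if cur and h[0] == cur[-1][0] and h[1] - cur[-1][2] <= merge_distance:
            cur.append(h)
        else:
            _flush_candidate(cur, candidates)
            cur = [h]
    _flush_candidate(cur, candidates)
    return candidates


def _flush_candidate(cur, candidates) -> None:
    if not cur:
        return
    groups = frozenset(h[3] for h in cur)
    candidates.append(
        RescueCandidate(
            contig=cur[0][0],
            start=cur[0][1],
            end=max(h[2] for h in cur),
            n_reads=len(cur),
            samples=groups,
            bplus_exclusive=groups == frozenset({"Bplus"}),
        )
    )


# ---------------------------------------------------------------------------
# qPCR gene dose ratio (ddCq)
# ---------------------------------------------------------------------------

def gene_dose_ratio(
    cq_table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "UBCE",
    group_a: str = "Bminus",
    group_b: str = "Bplus",
    alpha: float = 0.05,
) -> GDRResult:
    """Relative gene dose between two groups by the 2^-ddCq method.

    ``cq_table`` has columns (sample, gene, cq, group). Per sample,
    dCq = Cq(target) - Cq(reference); ddCq = mean dCq(group_b) - mean
    dCq(group_a); dose_ratio = 2^-ddCq. Significance from a two-sided
    Wilcoxon rank-sum test on the per-sample dCq values. Samples missing
    either gene are excluded with a log entry; fewer than 2 usable samples
    per group is an error.
    """
    dcq: dict[str, list[float]] = {group_a: [], group_b: []}
    for (sample, group), sub in cq_table.groupby(["sample", "group"]):
        if group not in dcq:
            continue
        by_gene = sub.groupby("gene")["cq"].mean()
        if target_gene not in by_gene.index or reference_gene not in by_gene.index:
            log.info("sample %s: missing %s or %s, excluded", sample, target_gene, reference_gene)
            continue
        dcq[group].append(float(by_gene[target_gene]) - float(by_gene[reference_gene]))
    for group, values in dcq.items():
        if len(values) < 2:
            raise ValueError(f"group {group}: fewer than 2 usable samples for {target_gene}")
    ddcq = float(np.mean(dcq[group_b]) - np.mean(dcq[group_a]))
    p = float(stats.ranksums(dcq[group_b], dcq[group_a]).pvalue)
    return GDRResult(
        target_gene=target_gene,
        delta_delta_cq=ddcq,
        dose_ratio=2.0 ** (-ddcq),
        p_value=p,
        significant=p < alpha,
    )
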