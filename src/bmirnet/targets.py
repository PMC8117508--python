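"""miRNA target prediction on 3'UTRs by canonical seed matching.

Implements 3'UTR extraction from oriented transcripts, a scanner for the
three canonical seed-site types, and an additive context score with a strict
significance cutoff at -0.2 (more negative = more favorable).

Site taxonomy (antiparallel Watson-Crick pairing between the miRNA 5' seed
and the UTR): a 6-nt "core" in the UTR is the reverse complement of miRNA
positions 2-7. The UTR base immediately 5' of the core pairs miRNA position
8 (the m8 match); the UTR base immediately 3' of the core sits opposite
miRNA position 1 and defines the 1A anchor when it is an A:

  8mer     = core + m8 match + 3'-adjacent A
  7mer-m8  = core + m8 match, no A
  7mer-1A  = core + A, no m8 match

U and T are treated as equivalent on input; the internal alphabet is DNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalog import _norm, revcomp

log = logging.getLogger(__name__)

#: per-site score contributions; implementation constants patterned on mean
#: context contributions of the canonical site types, configurable per call.
DEFAULT_SITE_SCORES = {"8mer": -0.31, "7mer-m8": -0.16, "7mer-1A": -0.10}

SIGNIFICANCE_CUTOFF = -0.2

_TYPE_RANK = {"8mer": 0, "7mer-m8": 1, "7mer-1A": 2}


@dataclass
class UTRRecord:
    transcript_id: str
    sequence: str
    tissue_expression: frozenset[str] = frozenset()
    gene_symbol: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"UTR {self.transcript_id}: empty sequence")
        self.sequence = _norm(self.sequence)
        self.tissue_expression = frozenset(self.tissue_expression)


@dataclass
class SeedSite:
    site_type: str
    utr_position: int  # 0-based start of the seed-paired region
    score_contribution: float = 0.0


@dataclass
class TargetInteraction:
    mirna_id: str
    transcript_id: str
    sites: list[SeedSite] = field(default_factory=list)
    total_score: float = 0.0
    significant: bool = False


# ---------------------------------------------------------------------------
# 3'UTR extraction
# ---------------------------------------------------------------------------

def find_longest_orf(seq: str, min_codons: int = 100) -> tuple[int, int] | None:
    """Longest forward-frame ORF (ATG..stop, stop included), 0-based half-open.

    Transcripts are assumed oriented on the coding strand, so only the three
    forward frames are scanned. Returns None when no ORF reaches
    ``min_codons`` (count includes the stop codon).
    """
    s = _norm(seq)
    stops = {"TAA", "TAG", "TGA"}
    best: tuple[int, int] | None = None
    for frame in range(3):
        start = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if start is None and codon == "ATG":
                start = i
            elif start is not None and codon in stops:
                n_codons = (i + 3 - start) // 3
                if n_codons >= min_codons and (best is None or i + 3 - start > best[1] - best[0]):
                    best = (start, i + 3)
                start = None
    return best


def extract_utrs(
    transcripts: Mapping[str, str],
    orf_annotations: Mapping[str, tuple[int, int]] | None = None,
    annotation: Mapping[str, tuple[frozenset[str], str | None]] | None = None,
    min_codons: int = 100,
) -> list[UTRRecord]:
    """3'UTRs: the subsequence strictly downstream of the stop codon.

    ``orf_annotations`` maps transcript id -> (orf_start, orf_end) 0-based
    half-open with the stop codon included in the ORF; without it, the
    longest forward-frame ORF is located first. Transcripts whose ORF ends at
    the transcript end (no downstream sequence) are skipped with a log entry;
    malformed coordinates are reported per record and processing continues.
    ``annotation`` optionally maps transcript id -> (tissues, gene_symbol).
    """
    out: list[UTRRecord] = []
    for tid, seq in transcripts.items():
        seq = _norm(seq)
        if orf_annotations is not None and tid in orf_annotations:
            start, end = orf_annotations[tid]
            if not (0 <= start < end <= len(seq)):
                log.error("transcript %s: ORF coordinates (%s, %s) out of bounds", tid, start, end)
                continue
        else:
            orf = find_longest_orf(seq, min_codons=min_codons)
            if orf is None:
                log.info("transcript %s: no ORF found, skipped", tid)
                continue
            start, end = orf
        utr = seq[end:]
        if not utr:
            log.info("transcript %s: ORF ends at transcript end, skipped", tid)
            continue
        tissues, symbol = frozenset(), None
        if annotation is not None and tid in annotation:
            tissues, symbol = annotation[tid]
        out.append(UTRRecord(tid, utr, tissues, symbol))
    return out


# ---------------------------------------------------------------------------
# Seed-site scanning
# ---------------------------------------------------------------------------

def find_seed_sites(
    mirna_sequence: str,
    utr_sequence: str,
    site_scores: Mapping[str, float] = DEFAULT_SITE_SCORES,
    min_spacing: int = 7,
) -> list[SeedSite]:
    """Scan a UTR for canonical seed sites of a mature miRNA.

    Finds every occurrence of the 6-nt core (reverse complement of miRNA
    positions 2-7), classifies it by the m8 match and the 3'-adjacent A, and
    resolves candidates within ``min_spacing`` nt of each other by keeping
    the stronger type (8mer > 7mer-m8 > 7mer-1A), then the 5'-most. The
    reported position is the 0-based start of the seed-paired region (the m8
    base for m8-containing sites, the core for 7mer-1A).
    """
    mir = _norm(mirna_sequence)
    if len(mir) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    utr = _norm(utr_sequence)
    core = revcomp(mir[1:7])
    m8_pair = revcomp(mir[7])
    candidates: list[SeedSite] = []
    i = utr.find(core)
    while i != -1:
        m8 = i > 0 and utr[i - 1] == m8_pair
        a1 = i + 6 < len(utr) and utr[i + 6] == "A"
        site_type = None
        if m8 and a1:
            site_type, pos = "8mer", i - 1
        elif m8:
            site_type, pos = "7mer-m8", i - 1
        elif a1:
            site_type, pos = "7mer-1A", i
        if site_type is not None:
            candidates.append(SeedSite(site_type, pos, site_scores[site_type]))
        i = utr.find(core, i + 1)
    # resolve overlaps: stronger type wins, then the 5'-most
    candidates.sort(key=lambda s: (_TYPE_RANK[s.site_type], s.utr_position))
    chosen: list[SeedSite] = []
    for cand in candidates:
        if all(abs(cand.utr_position - c.utr_position) > min_spacing for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda s: s.utr_position)
    return chosen


def score_interaction(
    mirna_id: str,
    transcript_id: str,
    sites: Sequence[SeedSite],
    site_scores: Mapping[str, float] = DEFAULT_SITE_SCORES,
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> TargetInteraction:
    """Additive context score; significant iff strictly below the cutoff."""
    total = 0.0
    scored = []
    for site in sites:
        if site.site_type not in site_scores:
            raise ValueError(f"unknown site type {site.site_type!r}")
        contribution = site_scores[site.site_type]
        scored.append(SeedSite(site.site_type, site.utr_position, contribution))
        total += contribution
    return TargetInteraction(
        mirna_id, transcript_id, scored, round(total, 10), total < cutoff
    )


def predict_all(
    mirnas: Mapping[str, str],
    utrs: Iterable[UTRRecord],
    tissue: str | None = None,
    site_scores: Mapping[str, float] = DEFAULT_SITE_SCORES,
    cutoff: float = SIGNIFICANCE_CUTOFF,
) -> list[TargetInteraction]:
    """All significant interactions, restricted to UTRs expressed in a tissue.

    ``mirnas`` maps mature id -> sequence. Output ordering is deterministic:
    (mirna_id, transcript_id).
    """
    utr_list = sorted(utrs, key=lambda u: u.transcript_id)
    out: list[TargetInteraction] = []
    for mid in sorted(mirnas):
        seq = mirnas[mid]
        for utr in utr_list:
            if tissue is not None and tissue not in utr.tissue_expression:
                continue
            sites = find_seed_sites(seq, utr.sequence, site_scores)
            if not sites:
                continue
            inter = score_interaction(mid, utr.transcript_id, sites, site_scores, cutoff)
            if inter.significant:
                out.append(inter)
    return out
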