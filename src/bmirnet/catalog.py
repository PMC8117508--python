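"""miRNA catalog construction.

Builds a genome-wide microRNA catalog from small-RNA reads: adapter trimming
and length filtering, collapsing of a reference mature-miRNA list to a
nonredundant set, a simplified hairpin (inverted-repeat) detector that stands
in for full probabilistic precursor scoring, known/novel classification by
mature-sequence and seed similarity, dominant-arm assignment from read counts,
genomic clustering of precursors within 5 kb, and catalog summary statistics.

Coordinates are 0-based half-open internally; GFF3 emission converts to
1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

#: seed = nucleotides 2-8 from the mature 5' end (0-based slice [1:8])
SEED_START = 1
SEED_END = 8


def _norm(seq: str) -> str:
    """Uppercase and convert U->T; the internal alphabet is DNA."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return _norm(seq).translate(DNA_COMPLEMENT)[::-1]


def seed_of(sequence: str) -> str:
    """7-nt seed: positions 2-8 from the 5' end."""
    s = _norm(sequence)
    if len(s) < SEED_END:
        raise ValueError(f"sequence shorter than {SEED_END} nt has no seed: {s!r}")
    return s[SEED_START:SEED_END]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MatureMiRNA:
    """A mature miRNA arm with its seed (nt 2-8) and read support."""

    id: str
    sequence: str
    arm: str  # "5p" or "3p"
    read_count: int = 0

    def __post_init__(self) -> None:
        self.sequence = _norm(self.sequence)
        if not 17 <= len(self.sequence) <= 27:
            raise ValueError(
                f"mature {self.id}: length {len(self.sequence)} outside [17, 27]"
            )
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"mature {self.id}: arm must be 5p or 3p")
        if self.read_count < 0:
            raise ValueError(f"mature {self.id}: negative read count")

    @property
    def seed(self) -> str:
        return seed_of(self.sequence)


@dataclass
class PreMiRNA:
    """A precursor hairpin with up to two mature arms."""

    id: str
    contig: str
    start: int
    end: int
    strand: str = "+"
    mature_5p: MatureMiRNA | None = None
    mature_3p: MatureMiRNA | None = None
    status: str = "novel"  # "known" or "novel"
    seed_family: str | None = None
    dominant_arm: str = "5p"
    arm_tie: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"precursor {self.id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"precursor {self.id}: strand must be + or -")

    @property
    def matures(self) -> list[MatureMiRNA]:
        return [m for m in (self.mature_5p, self.mature_3p) if m is not None]


@dataclass
class MiRNACluster:
    """Precursors on one contig chained by inter-precursor gaps <= max_gap."""

    contig: str
    members: list[str]
    span: tuple[int, int]


@dataclass
class CatalogSummary:
    n_total: int
    n_known: int
    n_novel: int
    n_clustered: int
    n_minus: int
    n_plus: int
    n_5p_dominant: int
    pct_known: float = field(init=False)
    pct_novel: float = field(init=False)
    pct_clustered: float = field(init=False)
    pct_minus: float = field(init=False)
    pct_plus: float = field(init=False)
    pct_5p_dominant: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("empty catalog")
        if self.n_known + self.n_novel != self.n_total:
            raise ValueError("known + novel must equal total")
        for name in ("known", "novel", "clustered", "minus", "plus", "5p_dominant"):
            count = getattr(self, f"n_{name}")
            setattr(self, f"pct_{name}", pct(count, self.n_total))


def pct(count: int, total: int) -> float:
    """Percentage rounded half-even to 2 decimals (banker's rounding)."""
    return round(100.0 * count / total, 2)


# ---------------------------------------------------------------------------
# Read preprocessing
# ---------------------------------------------------------------------------

@dataclass
class TrimReport:
    n_input: int
    n_trimmed: int
    n_dropped: int
    n_retained: int


def trim_and_filter_reads(
    reads: Iterable[str],
    adapter: str = "TGGAA",
    min_len: int = 17,
    max_len: int = 27,
) -> tuple[list[str], TrimReport]:
    """Trim 3' adapters and drop reads outside the mature length window.

    Each read is truncated at the first occurrence of ``adapter`` (the adapter
    and everything downstream removed). Reads whose trimmed length falls
    outside ``[min_len, max_len]`` are dropped.
    """
    if not adapter:
        raise ValueError("adapter must be a nonempty string")
    adapter = _norm(adapter)
    retained: list[str] = []
    n_input = n_trimmed = n_dropped = 0
    for read in reads:
        n_input += 1
        seq = _norm(read)
        cut = seq.find(adapter)
        if cut != -1:
            seq = seq[:cut]
            n_trimmed += 1
        if min_len <= len(seq) <= max_len:
            retained.append(seq)
        else:
            n_dropped += 1
    return retained, TrimReport(n_input, n_trimmed, n_dropped, len(retained))


def collapse_reference(
    matures: Mapping[str, str] | Sequence[tuple[str, str]],
) -> tuple[dict[str, str], dict[str, str]]:
    """Collapse a reference mature list to a nonredundant set.

    Exact duplicates and full-length substrings of a longer retained sequence
    collapse to one representative: the longest sequence, ties broken by the
    lexicographically smallest id. Returns ``(retained, mapping)`` where
    ``mapping`` sends each removed id to its representative's id.
    """
    items = list(matures.items()) if isinstance(matures, Mapping) else list(matures)
    items = [(mid, _norm(seq)) for mid, seq in items]
    # longest first so representatives are seen before their substrings
    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    retained: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for mid, seq in items:
        rep = None
        for rid, rseq in retained.items():
            if seq in rseq:
                rep = rid
                break
        if rep is None:
            retained[mid] = seq
        else:
            mapping[mid] = rep
    return retained, mapping


# ---------------------------------------------------------------------------
# Hairpin detection (simplified inverted-repeat test)
# ---------------------------------------------------------------------------

#: Watson-Crick pairs plus the G.U (here G.T) wobble, both orientations.
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class HairpinCall:
    arm_len: int
    loop_len: int
    complementarity: float
    arm1: str
    loop: str
    arm2: str


def arm_complementarity(arm1: str, arm2: str) -> float:
    """Fraction of positions of arm1 pairing the reverse of arm2 (WC + G.U)."""
    a1, a2r = _norm(arm1), _norm(arm2)[::-1]
    n = min(len(a1), len(a2r))
    if n == 0:
        return 0.0
    paired = sum((a1[i], a2r[i]) in _PAIRS for i in range(n))
    return paired / n


def detect_hairpin(
    window: str,
    arm_len_range: tuple[int, int] = (20, 24),
    loop_range: tuple[int, int] = (8, 15),
    min_arm_complementarity: float = 0.6,
) -> HairpinCall | None:
    """Test a window for an inverted-repeat hairpin (arm / loop / arm).

    Considers every (arm length, loop length) partition of the full window
    into equal-length arms around a central loop and scores the fraction of
    Watson-Crick (plus G.U) paired positions between the 5' arm and the
    reverse of the 3' arm. Returns the best-scoring call iff it reaches
    ``min_arm_complementarity``, else None; longer arms win ties. A window
    admitting no valid partition yields None (a no-call, not an error).
    Genome-scale scanning slides this test over candidate windows.
    """
    seq = _norm(window)
    best: HairpinCall | None = None
    for arm_len in range(arm_len_range[0], arm_len_range[1] + 1):
        loop_len = len(seq) - 2 * arm_len
        if not loop_range[0] <= loop_len <= loop_range[1]:
            continue
        arm1 = seq[:arm_len]
        loop = seq[arm_len : arm_len + loop_len]
        arm2 = seq[arm_len + loop_len :]
        score = arm_complementarity(arm1, arm2)
        # longer arms win at equal complementarity
        if best is None or (score, arm_len) > (best.complementarity, best.arm_len):
            best = HairpinCall(arm_len, loop_len, score, arm1, loop, arm2)
    if best is not None and best.complementarity >= min_arm_complementarity:
        return best
    return None


# ---------------------------------------------------------------------------
# Classification, arm dominance, clustering
# ---------------------------------------------------------------------------

def _mismatches(a: str, b: str) -> int:
    """Hamming-style mismatch count; length difference counts as mismatches."""
    n = min(len(a), len(b))
    return sum(a[i] != b[i] for i in range(n)) + abs(len(a) - len(b))


def classify_precursor(
    pre: PreMiRNA, reference: Mapping[str, str]
) -> tuple[str, str | None]:
    """Classify a precursor as known or novel against a reference mature set.

    Known iff some mature arm matches a reference mature with <= 2 full-length
    mismatches AND an identical seed. Novel precursors whose seed exactly
    matches a reference seed inherit that reference id as seed family (ties:
    fewest full-sequence mismatches, then lexicographic id).
    """
    if not pre.matures:
        raise ValueError(f"precursor {pre.id}: no mature arm present")
    if not reference:
        log.warning("empty reference: all precursors classified novel")
        return "novel", None
    ref = {rid: _norm(seq) for rid, seq in reference.items()}
    best_known: tuple[int, str] | None = None
    for mat in pre.matures:
        for rid, rseq in ref.items():
            if len(rseq) < SEED_END:
                continue
            if seed_of(rseq) == mat.seed and _mismatches(mat.sequence, rseq) <= 2:
                cand = (_mismatches(mat.sequence, rseq), rid)
                if best_known is None or cand < best_known:
                    best_known = cand
    if best_known is not None:
        return "known", best_known[1]
    # seed-family search for novel precursors
    best_family: tuple[int, str] | None = None
    for mat in pre.matures:
        for rid, rseq in ref.items():
            if len(rseq) < SEED_END:
                continue
            if seed_of(rseq) == mat.seed:
                cand = (_mismatches(mat.sequence, rseq), rid)
                if best_family is None or cand < best_family:
                    best_family = cand
    return "novel", best_family[1] if best_family else None


def assign_dominant_arm(count_5p: int, count_3p: int) -> tuple[str, bool]:
    """Arm with strictly more reads; ties (including 0/0) go to 5p, flagged."""
    if count_5p < 0 or count_3p < 0:
        raise ValueError("read counts must be nonnegative")
    if count_5p == count_3p:
        return "5p", True
    return ("5p", False) if count_5p > count_3p else ("3p", False)


def cluster_mirnas(
    precursors: Sequence[PreMiRNA], max_gap: int = 5000
) -> tuple[list[MiRNACluster], list[str]]:
    """Single-linkage chaining of precursors within ``max_gap`` on one contig.

    Per contig, precursors sorted by start are chained while the gap
    (next.start - prev.end) is <= max_gap; overlaps (gap <= 0) join. Returns
    clusters of size >= 2 and the ids of singletons. Strand is ignored.
    """
    by_contig: dict[str, list[PreMiRNA]] = {}
    for p in precursors:
        by_contig.setdefault(p.contig, []).append(p)
    clusters: list[MiRNACluster] = []
    singletons: list[str] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda p: (p.start, p.end, p.id))
        chain: list[PreMiRNA] = []
        for p in ordered:
            if chain and p.start - chain[-1].end <= max_gap:
                chain.append(p)
            else:
                _flush_chain(chain, contig, clusters, singletons)
                chain = [p]
        _flush_chain(chain, contig, clusters, singletons)
    return clusters, singletons


def _flush_chain(
    chain: list[PreMiRNA],
    contig: str,
    clusters: list[MiRNACluster],
    singletons: list[str],
) -> None:
    if not chain:
        return
    if len(chain) >= 2:
        clusters.append(
            MiRNACluster(
                contig=contig,
                members=[p.id for p in chain],
                span=(chain[0].start, max(p.end for p in chain)),
            )
        )
    else:
        singletons.append(chain[0].id)


def summarize_catalog(precursors: Sequence[PreMiRNA], max_gap: int = 5000) -> CatalogSummary:
    """Catalog composition counts and 2-decimal percentages."""
    if not precursors:
        raise ValueError("cannot summarize an empty catalog")
    clusters, _ = cluster_mirnas(precursors, max_gap=max_gap)
    n_clustered = sum(len(c.members) for c in clusters)
    return CatalogSummary(
        n_total=len(precursors),
        n_known=sum(p.status == "known" for p in precursors),
        n_novel=sum(p.status == "novel" for p in precursors),
        n_clustered=n_clustered,
        n_minus=sum(p.strand == "-" for p in precursors),
        n_plus=sum(p.strand == "+" for p in precursors),
        n_5p_dominant=sum(p.dominant_arm == "5p" for p in precursors),
    )


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------

def write_precursor_gff3(precursors: Sequence[PreMiRNA], path) -> None:
    """Emit precursors as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in precursors:
            attrs = [f"ID={p.id}", f"status={p.status}", f"dominant_arm={p.dominant_arm}"]
            if p.seed_family:
                attrs.append(f"seed_family={p.seed_family}")
            fh.write(
                "\t".join(
                    [
                        p.contig,
                        "bmirnet",
                        "pre_miRNA",
                        str(p.start + 1),
                        str(p.end),
                        ".",
                        p.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_precursor_gff3(path) -> list[PreMiRNA]:
    """Read precursors written by :func:`write_precursor_gff3`."""
    out: list[PreMiRNA] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, _, ftype, start, end, _, strand, _, attr_s = line.rstrip("\n").split("\t")
            if ftype != "pre_miRNA":
                continue
            attrs = dict(kv.split("=", 1) for kv in attr_s.split(";") if "=" in kv)
            out.append(
                PreMiRNA(
                    id=attrs.get("ID", f"pre_{len(out)}"),
                    contig=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    status=attrs.get("status", "novel"),
                    seed_family=attrs.get("seed_family"),
                    dominant_arm=attrs.get("dominant_arm", "5p"),
                )
            )
    return out
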