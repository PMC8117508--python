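"""Synthetic data generation with known ground truth.

Every pipeline input can be generated here with the statistical structure the
analysis assumes, so each downstream stage is testable against a planted
truth: genome contigs carrying two-arm inverted-repeat precursors (a fraction
of them clustered within 5 kb), paired B-/B+ depth tracks with 2x coverage
over planted B-blocks, small-RNA reads with arm bias and literal 3' adapter
suffixes, negative-binomial count matrices at a fixed biological coefficient
of variation with planted fold changes, 3'UTRs with planted canonical seed
sites, and interaction / integrity / GO / Cq tables with known contaminant
rows and dose ratios.

One integer seed drives one independent RNG stream per generator, so adding
or reordering generator calls does not perturb the others' output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import MatureMiRNA, PreMiRNA, revcomp
from .targets import find_seed_sites

# fixed per-generator stream ids (spawn keys alongside the user seed)
_STREAM_GENOME = 11
_STREAM_DEPTH = 23
_STREAM_READS = 37
_STREAM_COUNTS = 41
_STREAM_UTRS = 53
_STREAM_INTERACTIONS = 67

BASES = np.array(list("ACGT"))

TISSUES = ("brain", "gonad", "muscle")
SEXES = ("F", "M")


@dataclass
class SimConfig:
    """Simulation conditions.

    Defaults mirror the study conditions the pipeline was built for: 60x base
    genomic coverage with 2x depth over B-blocks, biological coefficient of
    variation 0.4, planted linear fold change 1.5, four replicates per group,
    and an 80% dominant-arm read bias.
    """

    seed: int = 0
    n_contigs: int = 5
    contig_len: int = 100_000
    n_precursors: int = 20
    cluster_fraction: float = 0.5
    n_bblocks: int = 5
    bblock_len: int = 10_000
    base_depth: float = 60.0
    bcv: float = 0.4
    n_replicates: int = 4
    planted_fc: float = 1.5
    arm_bias: float = 0.8
    n_utrs: int = 50
    site_plant_rate: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_contigs", "contig_len", "n_precursors", "n_bblocks",
                     "bblock_len", "n_replicates", "n_utrs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("cluster_fraction", "arm_bias", "site_plant_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_fc < 1:
            raise ValueError("planted_fc must be >= 1")
        if self.bcv < 0:
            raise ValueError("bcv must be >= 0")
        if self.base_depth < 0:
            raise ValueError("base_depth must be >= 0")


@dataclass
class SimTruth:
    """Ground truth of every planted feature."""

    precursor_coords: list[tuple[str, int, int, str, int | None]] = field(default_factory=list)
    bblock_coords: list[tuple[str, int, int]] = field(default_factory=list)
    de_mirnas: list[tuple[str, str, float]] = field(default_factory=list)
    planted_sites: list[tuple[str, str, str, int]] = field(default_factory=list)
    dominant_arms: dict[str, str] = field(default_factory=dict)
    precursor_ids: list[str] = field(default_factory=list)
    mature_seqs: dict[str, dict[str, str]] = field(default_factory=dict)
    accidental_sites: list[tuple[str, str, str, int]] = field(default_factory=list)
    shared_targets: set[str] = field(default_factory=set)
    dose_ratios: dict[str, float] = field(default_factory=dict)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


# ---------------------------------------------------------------------------
# Genome with planted hairpins and B-blocks
# ---------------------------------------------------------------------------

def gen_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Random contigs with planted inverted-repeat precursors and B-blocks.

    Precursors are two-arm inverted repeats (arms 20-24 nt reverse-
    complementary, loop 8-15 nt). A ``cluster_fraction`` of them is laid out
    in chains with inter-precursor gaps <= 5000 bases on one contig; the rest
    are isolated by > 5000 bases. B-blocks are placed window-aligned (1 kb)
    after all precursors on each contig, never overlapping them.
    """
    rng = _rng(config, _STREAM_GENOME)
    truth = SimTruth()
    contigs = {f"contig_{i}": list(_random_seq(rng, config.contig_len))
               for i in range(config.n_contigs)}
    contig_names = list(contigs)
    if config.n_precursors > 0 and not contig_names:
        raise ValueError("cannot plant precursors without contigs")

    # decide cluster layout: chains of size 2-3 for the clustered fraction
    n_clustered = int(round(config.cluster_fraction * config.n_precursors))
    if n_clustered == 1:
        n_clustered = 0  # a cluster needs >= 2 members
    chain_sizes: list[int] = []
    remaining = n_clustered
    while remaining >= 2:
        size = int(rng.integers(2, 4))
        size = min(size, remaining)
        if remaining - size == 1:
            size = remaining  # avoid stranding a single member
        chain_sizes.append(size)
        remaining -= size
    groups: list[tuple[int | None, int]] = [
        (cid, size) for cid, size in enumerate(chain_sizes)
    ]
    groups += [(None, 1)] * (config.n_precursors - sum(chain_sizes))

    cursors = {name: 0 for name in contig_names}
    ci = 0
    pre_count = 0
    precursor_spans: dict[str, list[tuple[int, int]]] = {n: [] for n in contig_names}
    for cluster_id, size in groups:
        placed = False
        for _ in range(len(contig_names)):
            name = contig_names[ci % len(contig_names)]
            # max footprint: size hairpins of <=63 nt + intra gaps <=2000
            need = 9000 + size * 63 + (size - 1) * 2000
            if cursors[name] + need <= len(contigs[name]):
                pos = cursors[name] + int(rng.integers(6000, 9000))
                for k in range(size):
                    arm_len = int(rng.integers(20, 25))
                    loop_len = int(rng.integers(8, 16))
                    arm1 = _random_seq(rng, arm_len)
                    loop = _random_seq(rng, loop_len)
                    hairpin = arm1 + loop + revcomp(arm1)
                    strand = "+" if rng.random() < 0.5 else "-"
                    insert = hairpin if strand == "+" else revcomp(hairpin)
                    start, end = pos, pos + len(hairpin)
                    if end > len(contigs[name]):
                        raise ValueError(f"contig {name} too short for requested features")
                    contigs[name][start:end] = list(insert)
                    pid = f"sim_mir_{pre_count}"
                    truth.precursor_ids.append(pid)
                    truth.precursor_coords.append((name, start, end, strand, cluster_id))
                    # transcript-space arms: 5p is the first arm of the hairpin
                    truth.mature_seqs[pid] = {"5p": arm1, "3p": revcomp(arm1)}
                    truth.dominant_arms[pid] = "5p" if rng.random() < 0.55 else "3p"
                    precursor_spans[name].append((start, end))
                    pre_count += 1
                    if k < size - 1:
                        pos = end + int(rng.integers(200, 2001))
                cursors[name] = end
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError("contigs too short to host requested precursors")
        ci += 1

    # B-blocks: window-aligned, after the precursor zone of each contig
    for b in range(config.n_bblocks):
        placed = False
        for name in contig_names:
            zone_start = ((cursors[name] + 6000) // 1000 + 1) * 1000
            if zone_start + config.bblock_len + 2000 <= len(contigs[name]):
                truth.bblock_coords.append((name, zone_start, zone_start + config.bblock_len))
                cursors[name] = zone_start + config.bblock_len + 1000
                placed = True
                break
        if not placed:
            raise ValueError("contigs too short to host requested B-blocks")

    return {name: "".join(seq) for name, seq in contigs.items()}, truth


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def gen_depth_tracks(
    genome: dict[str, str],
    truth: SimTruth,
    config: SimConfig,
    window: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed Poisson depth tracks for the B- and B+ genomic libraries.

    Per-window depth ~ Poisson(base_depth) everywhere, except B+ windows
    overlapping a planted B-block, which draw from Poisson(2 * base_depth).
    Returns two DataFrames with columns (contig, start, end, depth), 0-based
    half-open.
    """
    rng = _rng(config, _STREAM_DEPTH)
    blocks_by_contig: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in truth.bblock_coords:
        blocks_by_contig.setdefault(contig, []).append((start, end))
    rows_minus, rows_plus = [], []
    for contig in genome:
        length = len(genome[contig])
        for ws in range(0, length, window):
            we = min(ws + window, length)
            in_block = any(ws < be and we > bs
                           for bs, be in blocks_by_contig.get(contig, []))
            d_minus = rng.poisson(config.base_depth)
            d_plus = rng.poisson(config.base_depth * (2.0 if in_block else 1.0))
            rows_minus.append((contig, ws, we, float(d_minus)))
            rows_plus.append((contig, ws, we, float(d_plus)))
    cols = ["contig", "start", "end", "depth"]
    return pd.DataFrame(rows_minus, columns=cols), pd.DataFrame(rows_plus, columns=cols)


# ---------------------------------------------------------------------------
# Small-RNA reads
# ---------------------------------------------------------------------------

def gen_srna_reads(
    truth: SimTruth,
    config: SimConfig,
    reads_per_precursor: int = 200,
    adapter: str = "TGGAA",
    adapter_fraction: float = 0.3,
) -> list[tuple[str, str]]:
    """Reads drawn from mature arms with bias toward the true dominant arm.

    Reads are the mature arm sequence, optionally shortened by up to 2 nt at
    the 3' end (lengths stay within 17-27 after trimming). An
    ``adapter_fraction`` of reads carries the literal adapter plus a random
    tail as a 3' suffix. Read ids encode ``precursor|arm|index``.
    """
    if not truth.precursor_ids:
        raise ValueError("no precursors planted; generate a genome first")
    rng = _rng(config, _STREAM_READS)
    reads: list[tuple[str, str]] = []
    for pid in truth.precursor_ids:
        dom = truth.dominant_arms[pid]
        other = "3p" if dom == "5p" else "5p"
        for i in range(reads_per_precursor):
            arm = dom if rng.random() < config.arm_bias else other
            seq = truth.mature_seqs[pid][arm]
            seq = seq[: len(seq) - int(rng.integers(0, 3))]
            if rng.random() < adapter_fraction:
                seq = seq + adapter + _random_seq(rng, int(rng.integers(3, 7)))
            reads.append((f"{pid}|{arm}|{i}", seq))
    return reads


# ---------------------------------------------------------------------------
# Count matrix with planted differential expression
# ---------------------------------------------------------------------------

def gen_counts(
    truth: SimTruth,
    config: SimConfig,
    de_fraction: float = 0.2,
    mean_log: float = 4.0,
    mean_sd: float = 1.0,
    contrasts: tuple[tuple[str, str], ...] = (("gonad", "F"),),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial counts with planted fold changes in the B+ group.

    Counts for miRNA g in a sample are NB with per-group mean and dispersion
    bcv^2; for planted DE miRNAs the B+ mean is mu * planted_fc (up) or
    mu / planted_fc (down), the same set and directions in every contrast.
    Baseline means are lognormal. Returns (counts, design): counts is miRNAs
    x samples, design has columns (sample_id, tissue, sex, b_status).
    """
    rng = _rng(config, _STREAM_COUNTS)
    mirnas = [f"{pid}-{truth.dominant_arms[pid]}" for pid in truth.precursor_ids]
    if not mirnas:
        raise ValueError("no miRNAs in truth; generate a genome first")
    if not truth.de_mirnas:
        n_de = int(round(de_fraction * len(mirnas)))
        de_idx = rng.choice(len(mirnas), size=n_de, replace=False)
        for j, idx in enumerate(sorted(de_idx)):
            direction = "up" if j % 2 == 0 else "down"
            truth.de_mirnas.append((mirnas[idx], direction, config.planted_fc))
    de_map = {mid: (direction, fc) for mid, direction, fc in truth.de_mirnas}

    base_mu = np.exp(rng.normal(mean_log, mean_sd, size=len(mirnas)))
    phi = config.bcv ** 2
    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for tissue, sex in contrasts:
        for b_status in ("Bminus", "Bplus"):
            for rep in range(config.n_replicates):
                mu = base_mu.copy()
                if b_status == "Bplus":
                    for gi, mid in enumerate(mirnas):
                        if mid in de_map:
                            direction, fc = de_map[mid]
                            mu[gi] = mu[gi] * fc if direction == "up" else mu[gi] / fc
                if phi > 0:
                    r = 1.0 / phi
                    counts = rng.negative_binomial(r, r / (r + mu))
                else:
                    counts = rng.poisson(mu)
                sid = f"{tissue}_{sex}_{b_status}_{rep + 1}"
                columns[sid] = counts
                design_rows.append((sid, tissue, sex, b_status))
    counts_df = pd.DataFrame(columns, index=pd.Index(mirnas, name="mirna_id"))
    design_df = pd.DataFrame(design_rows, columns=["sample_id", "tissue", "sex", "b_status"])
    return counts_df, design_df


# ---------------------------------------------------------------------------
# 3'UTRs with planted seed sites
# ---------------------------------------------------------------------------

_SITE_TYPES = ("8mer", "7mer-m8", "7mer-1A")


def gen_utrs(
    truth: SimTruth,
    config: SimConfig,
    utr_len: int = 500,
    tissues: tuple[str, ...] = TISSUES,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random 3'UTRs with canonical seed sites planted for miRNA/UTR pairs.

    For each (dominant-arm miRNA, UTR) pair, with probability
    ``site_plant_rate`` one site of a random canonical type is written into
    the UTR with the flanking context that defines the type. Accidental seed
    matches in the background are re-randomized for a few passes where
    feasible; residual matches are recorded in ``truth.accidental_sites``.
    Returns (utrs, annotation): annotation maps each UTR to a gene symbol and
    the tissues it is expressed in.
    """
    rng = _rng(config, _STREAM_UTRS)
    mirnas = {f"{pid}-{truth.dominant_arms[pid]}": truth.mature_seqs[pid][truth.dominant_arms[pid]]
              for pid in truth.precursor_ids}
    utrs: dict[str, list[str]] = {}
    planted_spans: dict[str, list[tuple[int, int]]] = {}
    ann_rows = []
    for u in range(config.n_utrs):
        uid = f"utr_{u}"
        utrs[uid] = list(_random_seq(rng, utr_len))
        planted_spans[uid] = []
        expressed = [t for t in tissues if rng.random() < 0.7] or [tissues[0]]
        ann_rows.append((uid, f"GENE{u:04d}", ",".join(expressed)))

    for mid, mature in mirnas.items():
        seed7_rc = revcomp(mature[1:8])   # pairs miRNA positions 2-8
        core6_rc = revcomp(mature[1:7])   # pairs positions 2-7
        m8_pair = revcomp(mature[7])
        for uid, seq in utrs.items():
            if rng.random() >= config.site_plant_rate:
                continue
            site_type = _SITE_TYPES[int(rng.integers(0, 3))]
            pos = None
            for _ in range(50):  # find a slot clear of earlier plantings
                cand = int(rng.integers(1, utr_len - 12))
                if all(abs(cand - s) > 20 for s, _ in planted_spans[uid]):
                    pos = cand
                    break
            if pos is None:
                continue
            if site_type == "8mer":
                segment = seed7_rc + "A"
                report_pos = pos
            elif site_type == "7mer-m8":
                non_a = rng.choice([b for b in "CGT"])
                segment = seed7_rc + non_a
                report_pos = pos
            else:  # 7mer-1A: no m8 pairing immediately 5' of the core
                non_pair = rng.choice([b for b in "ACGT" if b != m8_pair])
                segment = non_pair + core6_rc + "A"
                report_pos = pos + 1
            seq[pos : pos + len(segment)] = list(segment)
            planted_spans[uid].append((pos, pos + len(segment)))
            truth.planted_sites.append((mid, uid, site_type, report_pos))

    # light cleanup of accidental core matches outside planted regions
    for mid, mature in mirnas.items():
        core6_rc = revcomp(mature[1:7])
        for uid, seq in utrs.items():
            spans = planted_spans[uid]
            for _ in range(5):
                s = "".join(seq)
                hit = _accidental_hit(s, core6_rc, spans)
                if hit is None:
                    break
                seq[hit] = str(rng.choice(BASES))

    utr_seqs = {uid: "".join(seq) for uid, seq in utrs.items()}
    planted_by_pair = {(m, u) for m, u, _, _ in truth.planted_sites}
    for mid, mature in mirnas.items():
        for uid, s in utr_seqs.items():
            expected = [p for p in truth.planted_sites if p[0] == mid and p[1] == uid]
            for site in find_seed_sites(mature, s):
                if not any(t == site.site_type and pos == site.utr_position
                           for _, _, t, pos in expected):
                    truth.accidental_sites.append((mid, uid, site.site_type, site.utr_position))
    del planted_by_pair
    annotation = pd.DataFrame(ann_rows, columns=["transcript_id", "gene_symbol", "tissues"])
    return utr_seqs, annotation


def _accidental_hit(seq: str, core: str, spans: list[tuple[int, int]]) -> int | None:
    start = 0
    while True:
        i = seq.find(core, start)
        if i == -1:
            return None
        if not any(s - 8 <= i <= e + 2 for s, e in spans):
            return i
        start = i + 1


# ---------------------------------------------------------------------------
# Interaction, integrity, GO and Cq tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticTables:
    interactions: pd.DataFrame
    interaction_flags: pd.DataFrame
    integrity: pd.DataFrame
    go_annotation: pd.DataFrame
    cq: pd.DataFrame
    per_group_targets: dict[str, set[str]]


def gen_interactions(
    truth: SimTruth,
    config: SimConfig,
    n_genes: int = 40,
    n_edges: int = 60,
    contaminant_rate: float = 0.2,
    allowed_mi: tuple[str, ...] = ("MI:0004", "MI:0018", "MI:0114"),
    taxid: int = 9606,
    n_shared_targets: int = 8,
    n_cq_samples: int = 4,
) -> SyntheticTables:
    """Interaction, integrity, GO and Cq tables with known contaminants.

    The interaction table contains a clean undirected edge set plus flagged
    contaminant rows: A-B/B-A duplicates, self-loops, rows with a foreign
    taxid, and rows with a disallowed MI code. The integrity table assigns
    each B-gene a coding-integrity percentage; the Cq table encodes the
    planted per-gene dose ratios via per-sample Cq values against a UBCE
    reference; per-group target sets share exactly ``truth.shared_targets``.
    """
    rng = _rng(config, _STREAM_INTERACTIONS)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]

    clean_edges: set[tuple[str, str]] = set()
    while len(clean_edges) < min(n_edges, n_genes * (n_genes - 1) // 2):
        a, b = rng.choice(n_genes, size=2, replace=False)
        clean_edges.add(tuple(sorted((genes[a], genes[b]))))
    rows, flags = [], []
    for a, b in sorted(clean_edges):
        mi = str(rng.choice(list(allowed_mi)))
        rows.append((a, b, taxid, taxid, mi))
        flags.append("clean")
        r = rng.random()
        if r < contaminant_rate:
            kind = rng.choice(["duplicate", "self_loop", "foreign_taxid", "bad_mi"])
            if kind == "duplicate":
                rows.append((b, a, taxid, taxid, mi))
            elif kind == "self_loop":
                rows.append((a, a, taxid, taxid, mi))
            elif kind == "foreign_taxid":
                rows.append((a, b, taxid, 10090, mi))
            else:
                rows.append((a, b, taxid, taxid, "MI:0428"))
            flags.append(str(kind))
    order = rng.permutation(len(rows))
    interactions = pd.DataFrame(
        [rows[i] for i in order],
        columns=["symbol_a", "symbol_b", "taxid_a", "taxid_b", "mi_code"],
    )
    flag_df = pd.DataFrame({"flag": [flags[i] for i in order]})

    # shared targets planted across all tissue groups
    shared = set(rng.choice(genes, size=min(n_shared_targets, n_genes), replace=False))
    truth.shared_targets = shared
    per_group: dict[str, set[str]] = {}
    leftovers = [g for g in genes if g not in shared]
    for t in TISSUES:
        extra = set(rng.choice(leftovers, size=min(5, len(leftovers)), replace=False))
        per_group[t] = shared | extra
        leftovers = [g for g in leftovers if g not in extra]
    # ensure group-specific extras never appear in every group
    inter = set.intersection(*per_group.values())
    assert inter == shared

    n_bgenes = min(10, n_genes)
    integrity = pd.DataFrame({
        "gene_name": genes[:n_bgenes],
        "protein_symbol": genes[:n_bgenes],
        "integrity": np.round(rng.uniform(30, 100, size=n_bgenes), 2),
    })

    terms = [f"GO:{7000000 + i}" for i in range(12)]
    go_rows = [(g, t) for g in genes for t in terms if rng.random() < 0.25]
    go_annotation = pd.DataFrame(go_rows, columns=["gene", "term"])

    # Cq table: planted dose ratios via delta-Cq against the UBCE reference
    cq_rows = []
    dose_genes = genes[: min(3, n_genes)]
    for gi, g in enumerate(dose_genes):
        ratio = [1.0, 2.0, 0.5][gi % 3]
        truth.dose_ratios[g] = ratio
        for group, shift in (("Bminus", 0.0), ("Bplus", -np.log2(ratio))):
            for s in range(n_cq_samples):
                ref_cq = 20.0 + rng.normal(0, 0.1)
                tgt_cq = ref_cq + 3.0 + shift + rng.normal(0, 0.1)
                sid = f"{g}_{group}_{s + 1}"
                cq_rows.append((sid, "UBCE", round(ref_cq, 3), group))
                cq_rows.append((sid, g, round(tgt_cq, 3), group))
    cq = pd.DataFrame(cq_rows, columns=["sample", "gene", "cq", "group"])
    return SyntheticTables(interactions, flag_df, integrity, go_annotation, cq, per_group)


# ---------------------------------------------------------------------------
# Writers (plain-text formats)
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_depth_tsv(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_depth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_gff3(truth: SimTruth, path) -> None:
    """Planted precursor and B-block coordinates as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid, (contig, start, end, strand, cid) in zip(
            truth.precursor_ids, truth.precursor_coords
        ):
            attrs = f"ID={pid}" + (f";cluster={cid}" if cid is not None else "")
            fh.write(f"{contig}\tsim\tpre_miRNA\t{start + 1}\t{end}\t.\t{strand}\t.\t{attrs}\n")
        for i, (contig, start, end) in enumerate(truth.bblock_coords):
            fh.write(f"{contig}\tsim\tb_block\t{start + 1}\t{end}\t.\t+\t.\tID=bblock_{i}\n")


def truth_precursors(truth: SimTruth) -> list[PreMiRNA]:
    """Truth coordinates as PreMiRNA objects (for clustering and intersection)."""
    out = []
    for pid, (contig, start, end, strand, _) in zip(
        truth.precursor_ids, truth.precursor_coords
    ):
        arms = truth.mature_seqs[pid]
        out.append(PreMiRNA(
            id=pid, contig=contig, start=start, end=end, strand=strand,
            mature_5p=MatureMiRNA(f"{pid}-5p", arms["5p"], "5p"),
            mature_3p=MatureMiRNA(f"{pid}-3p", arms["3p"], "3p"),
            dominant_arm=truth.dominant_arms[pid],
        ))
    return out


def truth_cluster_partition(truth: SimTruth) -> dict[int, list[str]]:
    """Map cluster id -> member precursor ids for the planted clusters."""
    part: dict[int, list[str]] = {}
    for pid, (_, _, _, _, cid) in zip(truth.precursor_ids, truth.precursor_coords):
        if cid is not None:
            part.setdefault(cid, []).append(pid)
    return part
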