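"""PPI-network integration of miRNA targets ("B-miR-net").

Defines B-related proteins as the cross-group intersection of per-tissue
target sets, filters a BioGRID-style interaction table down to nonredundant
human edges detected by an allowed set of PSI-MI experimental-method codes,
extracts the subnetwork induced on a seed protein set, merges directed
miRNA->protein regulatory edges into the graph, partitions B-genes by the
coding-integrity threshold (> 80% strictly), and runs hypergeometric GO-term
enrichment with Benjamini-Hochberg correction plus exclusive-term extraction.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: PSI-MI detection-method codes retained by default: affinity chromatography,
#: X-ray crystallography, far western blotting, FRET, protein complementation
#: assay, experimental interaction detection, two hybrid.
ALLOWED_MI = frozenset(
    {"MI:0004", "MI:0114", "MI:0047", "MI:0055", "MI:0090", "MI:0045", "MI:0018"}
)

HUMAN_TAXID = 9606

_MI_RE = re.compile(r"MI:\d{4}")


@dataclass
class InteractionRecord:
    symbol_a: str
    symbol_b: str
    taxid_a: int
    taxid_b: int
    mi_code: str


@dataclass
class GeneIntegrityRecord:
    gene_name: str
    protein_symbol: str
    integrity: float

    def __post_init__(self) -> None:
        if not 0 <= self.integrity <= 100:
            raise ValueError(
                f"{self.gene_name}: integrity {self.integrity} outside [0, 100]"
            )


@dataclass
class EnrichmentResult:
    term_id: str
    k: int
    K: int
    n: int
    N: int
    p_value: float
    q_value: float | None = None


@dataclass
class BMirNet:
    protein_nodes: set[str] = field(default_factory=set)
    mirna_nodes: set[str] = field(default_factory=set)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)
    regulatory_edges: set[tuple[str, str]] = field(default_factory=set)
    seed_provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.protein_nodes) + len(self.mirna_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.ppi_edges) + len(self.regulatory_edges)

    def degrees(self) -> dict[str, int]:
        deg: dict[str, int] = {n: 0 for n in self.protein_nodes | self.mirna_nodes}
        for a, b in self.ppi_edges:
            deg[a] += 1
            deg[b] += 1
        for m, p in self.regulatory_edges:
            deg[m] += 1
            deg[p] += 1
        return deg


# ---------------------------------------------------------------------------
# B-related proteins
# ---------------------------------------------------------------------------

def intersect_target_sets(
    per_group: Mapping[str, set[str]],
) -> tuple[set[str], dict[str, int]]:
    """Exact intersection of per-group target sets = the B-related proteins.

    Also reports Venn region counts keyed by sorted group combination (for
    the usual three-group diagram). Empty groups give an empty intersection
    with a warning.
    """
    if len(per_group) < 2:
        raise ValueError("need at least 2 groups to intersect")
    sets = {g: {_canon_symbol(s) for s in members} for g, members in per_group.items()}
    for g, members in sets.items():
        if not members:
            log.warning("group %s is empty; intersection is empty", g)
    shared = set.intersection(*sets.values()) if all(sets.values()) else set()
    venn: dict[str, int] = {}
    universe = set.union(*sets.values())
    for symbol in universe:
        key = "+".join(sorted(g for g, members in sets.items() if symbol in members))
        venn[key] = venn.get(key, 0) + 1
    return shared, venn


def _canon_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Interaction filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    n_input: int
    n_bad_taxid: int
    n_bad_mi: int
    n_self_loops: int
    n_duplicates: int
    n_malformed: int
    n_edges: int


def parse_mi_code(value: str) -> str | None:
    """Extract the MI:nnnn token from a detection-method field."""
    m = _MI_RE.search(str(value))
    return m.group(0) if m else None


def filter_interactions(
    records: Iterable[InteractionRecord] | pd.DataFrame,
    allowed_mi: frozenset[str] | set[str] = ALLOWED_MI,
    taxid: int = HUMAN_TAXID,
) -> tuple[set[tuple[str, str]], FilterReport]:
    """Filter to nonredundant undirected edges of one organism.

    Keeps rows where both taxids equal ``taxid`` and the MI code is allowed;
    canonicalizes each pair by sorted upper-cased symbols; drops self-loops
    and duplicates. Malformed rows are skipped with a log entry. Returns the
    edge set and per-rule removal counts.
    """
    if isinstance(records, pd.DataFrame):
        records = (
            InteractionRecord(
                str(r.symbol_a), str(r.symbol_b), int(r.taxid_a), int(r.taxid_b),
                str(r.mi_code),
            )
            for r in records.itertuples(index=False)
        )
    edges: set[tuple[str, str]] = set()
    n_input = n_bad_taxid = n_bad_mi = n_self = n_dup = n_malformed = 0
    for rec in records:
        n_input += 1
        try:
            a, b = _canon_symbol(rec.symbol_a), _canon_symbol(rec.symbol_b)
            if not a or not b:
                raise ValueError("empty symbol")
            mi = parse_mi_code(rec.mi_code)
        except (ValueError, AttributeError) as exc:
            log.info("malformed interaction row skipped: %s", exc)
            n_malformed += 1
            continue
        if rec.taxid_a != taxid or rec.taxid_b != taxid:
            n_bad_taxid += 1
            continue
        if mi is None or mi not in allowed_mi:
            n_bad_mi += 1
            continue
        if a == b:
            n_self += 1
            continue
        edge = (a, b) if a < b else (b, a)
        if edge in edges:
            n_dup += 1
            continue
        edges.add(edge)
    report = FilterReport(
        n_input, n_bad_taxid, n_bad_mi, n_self, n_dup, n_malformed, len(edges)
    )
    return edges, report


def read_interaction_table(
    path,
    col_symbol_a: int | str = 0,
    col_symbol_b: int | str = 1,
    col_taxid_a: int | str = 2,
    col_taxid_b: int | str = 3,
    col_mi: int | str = 4,
) -> pd.DataFrame:
    """Read a tab-delimited interaction table with configurable columns.

    Columns may be header names or 0-based indices (for headerless or
    BioGRID-tab3-style dumps where the relevant fields sit at known offsets).
    Taxid fields may carry a "taxid:9606" prefix; MI fields any text
    containing an MI:nnnn token.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    def col(c):
        return df.iloc[:, c] if isinstance(c, int) else df[c]
    out = pd.DataFrame(
        {
            "symbol_a": col(col_symbol_a),
            "symbol_b": col(col_symbol_b),
            "taxid_a": col(col_taxid_a).map(_parse_taxid),
            "taxid_b": col(col_taxid_b).map(_parse_taxid),
            "mi_code": col(col_mi),
        }
    )
    return out


def _parse_taxid(value: str) -> int:
    m = re.search(r"\d+", str(value))
    if m is None:
        raise ValueError(f"no taxid in {value!r}")
    return int(m.group(0))


# ---------------------------------------------------------------------------
# Subnetwork extraction and B-miR-net assembly
# ---------------------------------------------------------------------------

def extract_subnetwork(
    edges: Iterable[tuple[str, str]],
    seed_symbols: Iterable[str],
    neighbors: bool = False,
) -> nx.Graph:
    """Subgraph induced on a seed set; isolated seeds are dropped.

    With ``neighbors=True`` the seed set is first expanded by the seeds'
    first neighbors in the full network (both modes keep only edges with
    both endpoints in the final node set).
    """
    seeds = {_canon_symbol(s) for s in seed_symbols}
    if not seeds:
        raise ValueError("seed set must be nonempty")
    full = nx.Graph()
    full.add_edges_from(edges)
    nodes = set(seeds)
    if neighbors:
        for s in seeds & set(full.nodes):
            nodes.update(full.neighbors(s))
    sub = full.subgraph(nodes & set(full.nodes)).copy()
    sub.remove_nodes_from([n for n in list(sub.nodes) if sub.degree(n) == 0])
    return sub


def assemble_bmirnet(
    subgraph: nx.Graph,
    regulatory_edges: Iterable[tuple[str, str]],
    tissue_specific_targets: Mapping[str, set[str]] | None = None,
    b_genes: Iterable[str] = (),
    b_related: Iterable[str] = (),
) -> BMirNet:
    """Merge miRNA->protein regulatory edges into a PPI subgraph.

    Regulatory edges are deduplicated (multiple transcripts of one gene give
    one edge). A regulatory edge to a protein absent from both the subgraph
    and the tissue-specific target lists is dropped with a log entry. Node
    provenance labels: B-gene > B-related > neighbor for proteins in the
    subgraph; tissue-specific target for proteins only reached by miRNAs.
    """
    net = BMirNet()
    net.protein_nodes.update(_canon_symbol(n) for n in subgraph.nodes)
    for a, b in subgraph.edges:
        a, b = _canon_symbol(a), _canon_symbol(b)
        if a != b:
            net.ppi_edges.add((a, b) if a < b else (b, a))
    allowed_targets = set(net.protein_nodes)
    tissue_targets: set[str] = set()
    if tissue_specific_targets:
        for members in tissue_specific_targets.values():
            tissue_targets.update(_canon_symbol(s) for s in members)
        allowed_targets |= tissue_targets
    for mirna, protein in regulatory_edges:
        protein = _canon_symbol(protein)
        if protein not in allowed_targets:
            log.info("regulatory edge to unknown protein %s dropped", protein)
            continue
        net.mirna_nodes.add(mirna)
        net.protein_nodes.add(protein)
        net.regulatory_edges.add((mirna, protein))
    bg = {_canon_symbol(s) for s in b_genes}
    br = {_canon_symbol(s) for s in b_related}
    for node in net.protein_nodes:
        if node in bg:
            net.seed_provenance[node] = "B-gene"
        elif node in br:
            net.seed_provenance[node] = "B-related"
        elif node in tissue_targets and node not in set(map(_canon_symbol, subgraph.nodes)):
            net.seed_provenance[node] = "tissue-specific target"
        else:
            net.seed_provenance[node] = "neighbor"
    return net


def write_edge_list(net: BMirNet, path) -> None:
    rows = [(a, b, "ppi") for a, b in sorted(net.ppi_edges)]
    rows += [(m, p, "regulatory") for m, p in sorted(net.regulatory_edges)]
    pd.DataFrame(rows, columns=["source", "target", "kind"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# B-gene integrity
# ---------------------------------------------------------------------------

def integrity_partition(
    records: Sequence[GeneIntegrityRecord], threshold: float = 80.0
) -> tuple[list[GeneIntegrityRecord], list[GeneIntegrityRecord]]:
    """Split B-genes at the integrity threshold (strictly greater = above).

    Genes above the threshold have largely intact coding regions and are
    potentially translated; the rest may only produce truncated transcripts.
    Both lists are sorted by descending integrity.
    """
    above = sorted(
        (r for r in records if r.integrity > threshold),
        key=lambda r: -r.integrity,
    )
    at_or_below = sorted(
        (r for r in records if r.integrity <= threshold),
        key=lambda r: -r.integrity,
    )
    return above, at_or_below


def read_integrity_table(path_or_df) -> list[GeneIntegrityRecord]:
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df, sep="\t")
    )
    symbol_col = "protein_symbol" if "protein_symbol" in df.columns else df.columns[1]
    gene_col = "gene_name" if "gene_name" in df.columns else df.columns[0]
    return [
        GeneIntegrityRecord(str(r[gene_col]), str(r[symbol_col]), float(r["integrity"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def enrich_terms(
    selected: set[str],
    background: set[str],
    annotation: Mapping[str, set[str]] | pd.DataFrame,
    q_cutoff: float | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment with BH correction.

    ``annotation`` maps gene -> set of terms (or a two-column gene/term
    DataFrame). For each term with k >= 1 selected members, p is the
    probability of drawing >= k annotated genes in n = |selected| draws
    without replacement from N = |background| genes of which K carry the
    term. Terms with k = 0 are untested. Results sorted by p; optionally
    filtered at q < q_cutoff.
    """
    if not selected <= background:
        raise ValueError("selected genes must be a subset of the background")
    if isinstance(annotation, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for gene, term in annotation.itertuples(index=False):
            mapping.setdefault(str(gene), set()).add(str(term))
        annotation = mapping
    term_to_bg: dict[str, int] = {}
    term_to_sel: dict[str, int] = {}
    for gene in background:
        for term in annotation.get(gene, ()):
            term_to_bg[term] = term_to_bg.get(term, 0) + 1
            if gene in selected:
                term_to_sel[term] = term_to_sel.get(term, 0) + 1
    N, n = len(background), len(selected)
    results = []
    for term, k in term_to_sel.items():
        K = term_to_bg[term]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term, k, K, n, N, min(p, 1.0)))
    if results:
        q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, qv in zip(results, q):
            r.q_value = float(qv)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    if q_cutoff is not None:
        results = [r for r in results if r.q_value is not None and r.q_value < q_cutoff]
    return results


def exclusive_terms(
    terms_a: Iterable[str], terms_b: Iterable[str]
) -> tuple[set[str], set[str]]:
    """Terms enriched in A but not B, plus the shared set."""
    a, b = set(terms_a), set(terms_b)
    return a - b, a & b
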