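"""Post-discovery analyses: mRNA clustering, genomic proximity, network export.

Clustering groups the mRNAs that share a lncRNA:miRNA pair by expression
correlation (Ward agglomeration with Mojena's stopping rule); proximity
flags triplet member pairs whose gene intervals lie within a window on the
same chromosome; network export flattens triplets into node/edge tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

DEFAULT_CORR_THRESHOLD = 0.7
DEFAULT_MOJENA_C = 1.25          # Milligan & Cooper's correction constant
DEFAULT_WINDOW = 100_000


# ---------------------------------------------------------------------------
# genomic locations / GTF

@dataclass(frozen=True)
class GenomicLocation:
    rna_id: str
    chromosome: str
    start: int          # 1-based inclusive
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.rna_id}: start > end")
        if not self.chromosome:
            raise ValueError(f"{self.rna_id}: empty chromosome")


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf(path) -> dict[str, GenomicLocation]:
    """Gene locations from a 9-column GTF (feature type ``gene``)."""
    locations: dict[str, GenomicLocation] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: expected 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields
            if feature != "gene":
                continue
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise ValueError(f"{path}: gene record without gene_id")
            locations[m.group(1)] = GenomicLocation(
                rna_id=m.group(1), chromosome=chrom,
                start=int(start), end=int(end), strand=strand,
            )
    return locations


def write_gtf(locations, path, source: str = "spongescout") -> None:
    with open(path, "w") as fh:
        for loc in locations:
            fh.write(
                f"{loc.chromosome}\t{source}\tgene\t{loc.start}\t{loc.end}"
                f"\t.\t{loc.strand}\t.\tgene_id \"{loc.rna_id}\";\n"
            )


def interval_gap(a: GenomicLocation, b: GenomicLocation) -> int | None:
    """Bases strictly between two gene intervals; None across chromosomes.

    Overlapping or touching intervals have gap 0.  Strand is ignored.
    """
    if a.chromosome != b.chromosome:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end) - 1)


# ---------------------------------------------------------------------------
# mRNA clustering

@dataclass
class MrnaCluster:
    lncrna: str
    mirna: str
    members: list[str]
    cluster_index: int
    fusion_heights: list[float]


def mojena_cut(heights: np.ndarray, c: float = DEFAULT_MOJENA_C) -> int:
    """Number of clusters from fusion heights by Mojena's stopping rule.

    Scans merges in order; the first merge whose height exceeds
    mean(heights) + c * sd(heights) is refused, leaving n - j clusters
    where j merges were accepted.  Returns 1 when no merge is refused.
    """
    heights = np.asarray(heights, dtype=float)
    n_leaves = heights.size + 1
    if heights.size < 2:
        return 1
    crit = heights.mean() + c * heights.std(ddof=1)
    above = np.nonzero(heights > crit)[0]
    if above.size == 0:
        return 1
    return n_leaves - int(above[0])


def cluster_mrnas(
    corr: pd.DataFrame,
    lncrna: str = "",
    mirna: str = "",
    threshold: float = DEFAULT_CORR_THRESHOLD,
    mojena_c: float = DEFAULT_MOJENA_C,
) -> list[MrnaCluster]:
    """Cluster the mRNAs of one lncRNA:miRNA pair by expression correlation.

    If every off-diagonal correlation exceeds ``threshold`` all mRNAs form
    one cluster without agglomeration; otherwise Ward clustering on
    d = 1 - rho with the cluster count from Mojena's rule.
    """
    ids = list(corr.index)
    n = len(ids)
    if n == 1:
        return [MrnaCluster(lncrna, mirna, ids, 1, [])]
    cm = corr.to_numpy(dtype=float)
    if not np.allclose(cm, cm.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    off = cm[~np.eye(n, dtype=bool)]
    if (off > threshold).all():
        return [MrnaCluster(lncrna, mirna, ids, 1, [])]

    dist = 1.0 - cm
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="ward")
    heights = z[:, 2]
    k = mojena_cut(heights, mojena_c)
    labels = fcluster(z, t=k, criterion="maxclust")
    clusters = []
    for idx in sorted(set(labels)):
        members = [ids[i] for i in range(n) if labels[i] == idx]
        clusters.append(
            MrnaCluster(lncrna, mirna, members, int(idx), list(heights))
        )
    return clusters


def cluster_triplet_mrnas(
    triplets: list[dict], expr: pd.DataFrame, **kwargs
) -> list[MrnaCluster]:
    """Group triplets by lncRNA:miRNA pair and cluster each pair's mRNAs."""
    from scipy.stats import rankdata

    by_pair: dict[tuple[str, str], list[str]] = {}
    for t in triplets:
        by_pair.setdefault((t["lncrna"], t["mirna"]), []).append(t["mrna"])
    out: list[MrnaCluster] = []
    for (lnc, mir), mrnas in sorted(by_pair.items()):
        mrnas = sorted(set(mrnas))
        ranked = np.apply_along_axis(
            rankdata, 1, expr.loc[mrnas].to_numpy(dtype=float)
        )
        corr = pd.DataFrame(np.corrcoef(ranked) if len(mrnas) > 1 else [[1.0]],
                            index=mrnas, columns=mrnas)
        out.extend(cluster_mrnas(corr, lnc, mir, **kwargs))
    return out


# ---------------------------------------------------------------------------
# proximity

def proximal_triplets(
    triplets: list[dict],
    locations: dict[str, GenomicLocation],
    window: int = DEFAULT_WINDOW,
) -> list[dict]:
    """Annotate each triplet with member-pair proximity.

    A member pair is proximal iff both genes sit on the same chromosome
    with an interval gap <= ``window`` (inclusive boundary).  Members
    without a location are annotated as unknown, never dropped.
    """
    out = []
    for t in triplets:
        rec = dict(t)
        members = [("lncrna", t["lncrna"]), ("mirna", t["mirna"]),
                   ("mrna", t["mrna"])]
        missing = [rid for _, rid in members if rid not in locations]
        rec["location_missing"] = ",".join(missing)
        proximal_members: set[str] = set()
        for (ka, ra), (kb, rb) in (
            (members[0], members[1]),
            (members[0], members[2]),
            (members[1], members[2]),
        ):
            col = f"proximal_{ka}_{kb}"
            if ra in locations and rb in locations:
                gap = interval_gap(locations[ra], locations[rb])
                flag = gap is not None and gap <= window
                rec[col] = flag
                if flag:
                    proximal_members.update((ra, rb))
            else:
                rec[col] = None
        rec["n_proximal_members"] = len(proximal_members)
        rec["is_proximal"] = len(proximal_members) >= 2
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# network export

def export_network(triplets: list[dict]):
    """Flatten triplets into node/edge tables and sponge-count tables.

    Returns (nodes, edges, lnc_counts, mir_counts) DataFrames.  Edges are
    lncRNA:mRNA with the mediating miRNAs as an attribute; edge weight is
    the number of distinct mediating miRNAs.
    """
    edge_mirnas: dict[tuple[str, str], set[str]] = {}
    lnc_counts: dict[str, int] = {}
    mir_counts: dict[str, int] = {}
    for t in triplets:
        edge_mirnas.setdefault((t["lncrna"], t["mrna"]), set()).add(t["mirna"])
        lnc_counts[t["lncrna"]] = lnc_counts.get(t["lncrna"], 0) + 1
        mir_counts[t["mirna"]] = mir_counts.get(t["mirna"], 0) + 1

    edges = pd.DataFrame(
        [
            {"lncrna": lnc, "mrna": mrna,
             "mirnas": ",".join(sorted(mirs)), "weight": len(mirs)}
            for (lnc, mrna), mirs in sorted(edge_mirnas.items())
        ],
        columns=["lncrna", "mrna", "mirnas", "weight"],
    )

    degree: dict[str, int] = {}
    node_class: dict[str, str] = {}
    for (lnc, mrna), _ in edge_mirnas.items():
        degree[lnc] = degree.get(lnc, 0) + 1
        degree[mrna] = degree.get(mrna, 0) + 1
        node_class[lnc] = "lncRNA"
        node_class[mrna] = "mRNA"
    nodes = pd.DataFrame(
        [{"node": nid, "class": node_class[nid], "degree": degree[nid]}
         for nid in sorted(degree)],
        columns=["node", "class", "degree"],
    )
    lnc_tbl = pd.DataFrame(
        sorted(lnc_counts.items()), columns=["lncrna", "n_sponges"]
    )
    mir_tbl = pd.DataFrame(
        sorted(mir_counts.items()), columns=["mirna", "n_sponges"]
    )
    return nodes, edges, lnc_tbl, mir_tbl


def write_network_files(nodes: pd.DataFrame, edges: pd.DataFrame, prefix) -> None:
    """Write SIF and GraphML renderings plus the raw TSV tables."""
    prefix = str(prefix)
    nodes.to_csv(prefix + ".nodes.tsv", sep="\t", index=False)
    edges.to_csv(prefix + ".edges.tsv", sep="\t", index=False)
    with open(prefix + ".sif", "w") as fh:
        for _, e in edges.iterrows():
            fh.write(f"{e['lncrna']}\tceRNA\t{e['mrna']}\n")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node"], rna_class=row["class"], degree=int(row["degree"]))
    for _, e in edges.iterrows():
        g.add_edge(e["lncrna"], e["mrna"], weight=int(e["weight"]),
                   mirnas=e["mirnas"])
    nx.write_graphml(g, prefix + ".graphml")
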