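"""Persistence-weighted residue interaction networks from trajectories.

A residue interaction network (RIN) summarises an MD trajectory as a
graph: nodes are residues, and an edge between residues i and j carries
the *persistence* p_ij — the exact fraction of frames in which the two
side chains approach within a distance threshold (0.6 nm by default).
Approaches absent for more than 99 % of the trajectory are filtered out,
i.e. an edge is kept iff p_ij >= 0.01 under the strict d < threshold
rule.  Node selection is restricted to positions that are charged
(D/E/K/R) in at least one sequence of an orthologue alignment, which is
what makes the surviving graph a map of candidate electrostatic
clusters.

Distances are the minimum over side-chain heavy atoms of the two
residues (Calpha for glycine), in nm.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import AlignIO

__all__ = [
    "ChargeSelection",
    "TrajectoryDistances",
    "PersistenceNetwork",
    "select_charged_columns",
    "compute_pair_distances",
    "read_distances_csv",
    "persistence_matrix",
    "build_network",
    "write_network",
    "read_network",
    "cluster_report",
]

ACIDIC = set("DE")
BASIC = set("KR")  # histidine excluded: neutral at the pH 7.5 working conditions
CHARGED = ACIDIC | BASIC

DEFAULT_THRESHOLD_NM = 0.6
DEFAULT_MIN_PERSISTENCE = 0.01


@dataclass
class ChargeSelection:
    """Reference-protein positions charged in >=1 aligned orthologue.

    ``positions`` are 1-based residue indices in the reference sequence;
    ``charge_class`` maps each position to "acidic" or "basic" from the
    *reference* residue identity when the reference itself is charged,
    otherwise from the orthologue residue that contributed the charge.
    ``provenance`` records which sequences carried the charge at each
    selected column.
    """

    positions: list[int]
    charge_class: dict[int, str]
    provenance: dict[int, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)


def _charge_class_of(residue: str) -> str | None:
    if residue in ACIDIC:
        return "acidic"
    if residue in BASIC:
        return "basic"
    return None


def select_charged_columns(alignment_path, reference_id: str) -> ChargeSelection:
    """Select reference positions charged in at least one orthologue.

    Reads a FASTA multiple alignment, maps alignment columns to 1-based
    reference residue numbering through the reference row's non-gap
    positions, and keeps every position whose column contains at least
    one D/E/K/R in any sequence.  Columns where the reference is gapped
    are skipped.
    """
    try:
        alignment = AlignIO.read(str(alignment_path), "fasta")
    except ValueError as exc:
        raise ValueError(f"ragged or malformed alignment: {exc}") from exc
    lengths = {len(rec.seq) for rec in alignment}
    if len(lengths) != 1:
        raise ValueError("ragged alignment: sequences have unequal lengths")
    ref = next((rec for rec in alignment if rec.id == reference_id), None)
    if ref is None:
        raise KeyError(f"reference id {reference_id!r} not present in alignment")

    positions: list[int] = []
    charge_class: dict[int, str] = {}
    provenance: dict[int, list[str]] = {}
    ref_pos = 0
    for col in range(alignment.get_alignment_length()):
        ref_res = str(ref.seq[col]).upper()
        if ref_res == "-":
            continue
        ref_pos += 1
        carriers = [rec.id for rec in alignment
                    if str(rec.seq[col]).upper() in CHARGED]
        if not carriers:
            continue
        positions.append(ref_pos)
        provenance[ref_pos] = carriers
        cls = _charge_class_of(ref_res)
        if cls is None:
            donor = next(str(rec.seq[col]).upper() for rec in alignment
                         if str(rec.seq[col]).upper() in CHARGED)
            cls = _charge_class_of(donor)
        charge_class[ref_pos] = cls
    return ChargeSelection(positions, charge_class, provenance)


@dataclass
class TrajectoryDistances:
    """Per-frame minimum side-chain distances for selected residue pairs.

    ``pairs`` holds (i, j) residue indices with i < j; ``distances`` has
    shape (n_frames, n_pairs) in nm.
    """

    pairs: list[tuple[int, int]]
    distances: np.ndarray
    frame_stride_ps: float | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2 or self.distances.shape[1] != len(self.pairs):
            raise ValueError("distances must have shape (n_frames, n_pairs)")
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair indices must satisfy i < j, got ({i}, {j})")

    @property
    def n_frames(self) -> int:
        return self.distances.shape[0]


def compute_pair_distances(trajectory_path, selection: ChargeSelection) -> TrajectoryDistances:
    """Minimum side-chain heavy-atom distances from a multi-model PDB.

    For every pair of selected residues and every frame (PDB MODEL) the
    minimum distance over side-chain heavy atoms is computed, in nm;
    glycine falls back to Calpha.  Residues whose side-chain atoms are
    entirely missing trigger a warning and use whatever heavy atoms are
    present.
    """
    import MDAnalysis as mda
    from MDAnalysis.lib.distances import distance_array

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBs without elements/mass guesses
        u = mda.Universe(str(trajectory_path))
    if len(u.trajectory) == 0:
        raise ValueError("trajectory has zero frames")

    groups = {}
    for resid in selection.positions:
        res_atoms = u.select_atoms(f"resid {resid} and not name H* and not type H")
        if res_atoms.n_atoms == 0:
            raise ValueError(f"selected residue {resid} not present in trajectory")
        resname = res_atoms.residues.resnames[0]
        side = res_atoms.select_atoms("not backbone")
        if side.n_atoms == 0:
            # glycine (or stripped side chain): Calpha stands in
            side = res_atoms.select_atoms("name CA")
            if resname != "GLY":
                warnings.warn(
                    f"residue {resid} ({resname}) has no side-chain heavy atoms; "
                    "using available backbone atoms", stacklevel=2)
                side = res_atoms
        groups[resid] = side

    pairs = [(i, j) for a, i in enumerate(selection.positions)
             for j in selection.positions[a + 1:]]
    dist = np.empty((len(u.trajectory), len(pairs)), dtype=float)
    for f, _ts in enumerate(u.trajectory):
        for p, (i, j) in enumerate(pairs):
            d = distance_array(groups[i].positions, groups[j].positions)
            dist[f, p] = d.min() / 10.0  # angstrom -> nm
    return TrajectoryDistances(pairs, dist)


def read_distances_csv(path) -> TrajectoryDistances:
    """Read precomputed per-frame pair distances.

    Expected layout: columns ``frame`` then one column per pair named
    ``i-j`` (nm); or the long format with columns frame,res_i,res_j,distance_nm.
    """
    import pandas as pd

    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"frame", "res_i", "res_j", "distance_nm"} <= cols:
        wide = df.pivot_table(index="frame", columns=["res_i", "res_j"],
                              values="distance_nm")
        pairs = [(int(i), int(j)) for i, j in wide.columns]
        return TrajectoryDistances(pairs, wide.to_numpy())
    pair_cols = [c for c in df.columns if c != "frame"]
    pairs = []
    for c in pair_cols:
        i, j = c.split("-")
        pairs.append((int(i), int(j)))
    return TrajectoryDistances(pairs, df[pair_cols].to_numpy())


def persistence_matrix(distances: TrajectoryDistances,
                       threshold: float = DEFAULT_THRESHOLD_NM) -> dict[tuple[int, int], float]:
    """Per-pair persistence: fraction of frames with d < threshold.

    The boundary is strict — a frame at exactly the threshold does not
    count as an approach.  Counts are exact integers divided by the
    frame count, so values like 30/1000 are reported exactly as 0.030.
    """
    if distances.n_frames < 1:
        raise ValueError("need at least one frame")
    counts = (distances.distances < threshold).sum(axis=0)
    n = distances.n_frames
    return {pair: int(c) / n for pair, c in zip(distances.pairs, counts)}


@dataclass
class PersistenceNetwork:
    """RIN with charge-annotated nodes and persistence-weighted edges."""

    graph: nx.Graph
    threshold_nm: float
    min_persistence: float

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def isolated_nodes(self) -> list[int]:
        return [n for n in self.graph.nodes if self.graph.degree(n) == 0]


def build_network(distances: TrajectoryDistances, selection: ChargeSelection,
                  threshold: float = DEFAULT_THRESHOLD_NM,
                  min_persistence: float = DEFAULT_MIN_PERSISTENCE) -> PersistenceNetwork:
    """Build the filtered persistence network.

    An edge (i, j) survives iff the fraction of frames spent *beyond*
    the threshold is not greater than 1 - min_persistence; with the
    defaults this is the "farther than 0.6 nm for more than 99 % of the
    trajectory" filter, so p_ij >= 0.01 is retained and the 1 %
    boundary case is kept.  All selected residues appear as nodes;
    residues left without edges stay in the graph flagged isolated.
    """
    if not selection.positions:
        raise ValueError("empty charge selection: no nodes to build")
    pers = persistence_matrix(distances, threshold=threshold)
    g = nx.Graph()
    for resid in selection.positions:
        g.add_node(resid, label=f"res{resid}",
                   charge_class=selection.charge_class.get(resid, "unknown"))
    for (i, j), p in pers.items():
        if p >= min_persistence:
            g.add_edge(i, j, persistence=p)
    for n in g.nodes:
        g.nodes[n]["isolated"] = g.degree(n) == 0
    return PersistenceNetwork(g, threshold, min_persistence)


def write_network(network: PersistenceNetwork, path, format: str = "graphml") -> None:
    """Serialize to GraphML, edge-list CSV or DOT."""
    g = network.graph
    path = str(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "edgelist-csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["res_i", "res_j", "persistence"])
            for i, j, d in sorted(g.edges(data=True)):
                w.writerow([i, j, d["persistence"]])
    elif format == "dot":
        lines = ["graph RIN {"]
        for n, d in sorted(g.nodes(data=True)):
            lines.append(f'  {n} [label="{d.get("label", n)}" '
                         f'charge_class="{d.get("charge_class", "unknown")}"];')
        for i, j, d in sorted(g.edges(data=True)):
            lines.append(f'  {i} -- {j} [persistence="{d["persistence"]}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use graphml, edgelist-csv or dot")


def read_network(path, threshold: float = DEFAULT_THRESHOLD_NM,
                 min_persistence: float = DEFAULT_MIN_PERSISTENCE) -> PersistenceNetwork:
    """Read a GraphML file written by :func:`write_network`."""
    g = nx.read_graphml(str(path), node_type=int)
    return PersistenceNetwork(g, threshold, min_persistence)


def cluster_report(network: PersistenceNetwork,
                   secondary_structure: dict[int, str] | None = None) -> list[dict]:
    """Candidate electrostatic clusters: connected acidic components.

    Connected components of the subgraph induced by acidic nodes, sorted
    by size (descending) then summed edge persistence.  Singleton
    components are dropped: a lone residue is not a cluster of closely
    spaced charges.  If a per-residue
    secondary-structure annotation is given, each cluster reports whether
    its members span more than one element — the structural condition
    for destabilising like-charge repulsion across elements.
    """
    g = network.graph
    acidic = [n for n, d in g.nodes(data=True) if d.get("charge_class") == "acidic"]
    sub = g.subgraph(acidic)
    clusters = []
    for comp in nx.connected_components(sub):
        if len(comp) < 2:
            continue
        members = sorted(comp)
        total_p = sum(d["persistence"] for _, _, d in sub.subgraph(comp).edges(data=True))
        entry = {
            "members": members,
            "size": len(members),
            "total_persistence": total_p,
        }
        if secondary_structure is not None:
            elements = {secondary_structure.get(m) for m in members} - {None}
            entry["elements"] = sorted(elements)
            entry["spans_multiple_elements"] = len(elements) > 1
        clusters.append(entry)
    clusters.sort(key=lambda c: (-c["size"], -c["total_persistence"], c["members"]))
    return clusters
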