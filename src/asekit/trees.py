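"""Trees, fossil tip ages, and a-posteriori time-scaling.

Fossil phylogenies come with topology but no meaningful branch lengths;
analyses on time trees need every branch to span a positive amount of time.
This module reads rooted trees (Newick/NEXUS via dendropy), attaches first/last
appearance data (FAD/LAD, in Ma before present), and produces dated trees with
the two standard a-posteriori scalers:

* ``timescale_equal`` -- zero-length branches borrow time from the first
  preceding branch of positive length, shared equally (the "equal" method).
* ``timescale_mbl`` -- every branch is stretched to a minimum length by
  pushing parent nodes back in time (the "minimum branch length" method).

Ages increase into the past; a branch length is the age difference between
parent and child. Tips are dated at their FAD (the oldest plausible age).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd

__all__ = [
    "TaxonAges",
    "TimeTree",
    "read_tree",
    "read_ages",
    "timescale_equal",
    "timescale_mbl",
    "drop_tip",
]


class TreeError(ValueError):
    """Raised for malformed trees or age tables."""


# ---------------------------------------------------------------------------
# taxon ages
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonAges:
    """First/last appearance data for the tips of a fossil tree.

    ``fad[t]`` and ``lad[t]`` are ages in Ma before present with
    ``fad >= lad >= 0``. Tips are dated at FAD when time-scaling; LAD is
    retained for reporting and synthetic-data realism.
    """

    fad: Mapping[str, float]
    lad: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.fad) != set(self.lad):
            raise TreeError("FAD and LAD tables cover different taxa")
        for taxon in self.fad:
            f, l = float(self.fad[taxon]), float(self.lad[taxon])
            if not (f >= l >= 0.0):
                raise TreeError(
                    f"taxon {taxon!r}: FAD ({f}) must be >= LAD ({l}) >= 0"
                )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TaxonAges":
        cols = {c.lower(): c for c in frame.columns}
        missing = {"taxon", "fad", "lad"} - set(cols)
        if missing:
            raise TreeError(f"age table lacks columns: {sorted(missing)}")
        taxa = frame[cols["taxon"]].astype(str)
        if taxa.duplicated().any():
            dup = taxa[taxa.duplicated()].iloc[0]
            raise TreeError(f"duplicate taxon in age table: {dup!r}")
        fad = dict(zip(taxa, frame[cols["fad"]].astype(float)))
        lad = dict(zip(taxa, frame[cols["lad"]].astype(float)))
        return cls(fad=fad, lad=lad)

    def to_frame(self) -> pd.DataFrame:
        taxa = sorted(self.fad)
        return pd.DataFrame(
            {"taxon": taxa, "FAD": [self.fad[t] for t in taxa], "LAD": [self.lad[t] for t in taxa]}
        )

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.fad


def read_ages(path: str | Path) -> TaxonAges:
    """Read a ``taxon,FAD,LAD`` table (CSV, or TSV by extension/sniffing)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return TaxonAges.from_frame(pd.read_csv(path, sep=sep))


# ---------------------------------------------------------------------------
# time trees
# ---------------------------------------------------------------------------


class TimeTree:
    """A rooted tree with node ages (Ma) and branch lengths (myr).

    Wraps a :class:`dendropy.Tree`; every node carries an ``age`` attribute and
    every edge length equals ``parent.age - child.age``. ``root_length`` is the
    length of the stem edge above the root node (possibly 0 after the equal
    scaler has consumed it). Internal nodes get stable labels ``N0, N1, ...``
    in preorder when not already labelled.
    """

    def __init__(self, tree: dendropy.Tree, root_length: float = 0.0):
        self.tree = tree
        self.root_length = float(root_length)
        self._label_internals()

    # -- construction helpers -------------------------------------------------

    def _label_internals(self) -> None:
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if not node.label:
                node.label = f"N{i}"
            i += 1

    @classmethod
    def from_ages(cls, topology: dendropy.Tree, ages: TaxonAges,
                  root_length: float = 0.0) -> "TimeTree":
        """Date tips at FAD and every internal node at its oldest child's age."""
        tree = topology.clone(depth=1)
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                taxon = node.taxon.label
                if taxon not in ages:
                    raise TreeError(f"no age entry for tip {taxon!r}")
                node.age = float(ages.fad[taxon])
            else:
                node.age = max(child.age for child in node.child_nodes())
        out = cls(tree, root_length=root_length)
        out.sync_edge_lengths()
        return out

    def sync_edge_lengths(self) -> None:
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            node.edge.length = (
                self.root_length if parent is None else parent.age - node.age
            )

    # -- views ----------------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else node.label

    def branch_lengths(self) -> dict[str, float]:
        """Edge lengths keyed by child-node label (excludes the root stem)."""
        return {
            self.node_label(n): n.edge.length
            for n in self.tree.preorder_node_iter()
            if n.parent_node is not None
        }

    def node_ages(self) -> dict[str, float]:
        return {self.node_label(n): n.age for n in self.tree.preorder_node_iter()}

    def copy(self) -> "TimeTree":
        clone = self.tree.clone(depth=1)
        out = TimeTree.__new__(TimeTree)
        out.tree = clone
        out.root_length = self.root_length
        return out

    def write_newick(self, path: str | Path | None = None) -> str:
        s = self.tree.as_string(schema="newick", suppress_rooting=True)
        if path is not None:
            Path(path).write_text(s)
        return s

    def __len__(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_tree(source: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree from a file path or a literal tree string.

    Duplicate tip labels and unreadable files raise :class:`TreeError`.
    Polytomies and existing branch lengths are preserved.
    """
    if schema not in {"newick", "nexus"}:
        raise TreeError(f"unsupported tree schema: {schema!r}")
    text: str
    p = Path(str(source))
    try:
        is_file = p.exists()
    except OSError:  # e.g. a literal newick string too long for a file name
        is_file = False
    if is_file:
        text = p.read_text()
    elif str(source).lstrip().startswith(("(", "#")):
        text = str(source)
    else:
        raise TreeError(f"cannot read tree source: {source!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises many parse error types
        raise TreeError(f"unparseable {schema} tree: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# time-scaling
# ---------------------------------------------------------------------------


def _initial_ages(topology: dendropy.Tree, ages: TaxonAges) -> TimeTree:
    return TimeTree.from_ages(topology, ages, root_length=0.0)


def _zero_edges(tt: TimeTree, order: str) -> list[dendropy.Node]:
    """Child nodes of zero-length edges, in the requested visit order.

    ``basal_first``: breadth-first from the root, so basal chains resolve
    before nested ones. ``legacy``: depth-first preorder (cladewise input
    order), diving each clade to its tips before the next.
    """
    if order == "legacy":
        nodes = [n for n in tt.tree.preorder_node_iter() if n.parent_node is not None]
    elif order == "basal_first":
        nodes = []
        queue = deque([tt.root])
        while queue:
            node = queue.popleft()
            for child in node.child_nodes():
                nodes.append(child)
                queue.append(child)
    else:
        raise TreeError(f"unknown ordering dialect: {order!r}")
    return nodes


def timescale_equal(
    topology: dendropy.Tree,
    ages: TaxonAges,
    root_length: float = 1.0,
    ordering: str = "basal_first",
) -> TimeTree:
    """Date a fossil tree by the "equal" method.

    Tips are placed at their FAD and each internal node, initially, at its
    oldest descendant's age, which typically creates zero-length branches.
    If the root itself subtends a zero-length branch it is pushed back by
    ``root_length`` (consuming the stem). Each remaining zero-length branch
    then takes an equal share of the first preceding (ancestral) branch of
    positive length: a donor branch of length L followed on the path by k
    zero-length branches is divided into k+1 equal pieces.

    ``ordering`` selects the dialect: the two resolve zero-length chains in a
    different node-visit order and can return different (equally valid) trees
    of identical topology. Both guarantee strictly positive branch lengths.
    """
    if root_length <= 0:
        raise TreeError("root_length must be positive")
    tt = _initial_ages(topology, ages)
    tt.root_length = root_length
    root = tt.root
    if any(root.age == c.age for c in root.child_nodes()):
        root.age += root_length
        tt.root_length = 0.0

    for node in _zero_edges(tt, ordering):
        parent = node.parent_node
        if parent is None or parent.age > node.age:
            continue  # positive already (possibly resolved by an earlier chain)
        # climb to the nearest ancestor strictly older than this node
        chain = [node, parent]
        anc = parent.parent_node
        while anc is not None and anc.age <= node.age:
            chain.append(anc)
            anc = anc.parent_node
        if anc is None:
            raise TreeError("zero-length chain reaches above the root")
        chain.append(anc)
        # chain[0]=node ... chain[-1]=anc: k+1 edges spanning anc.age - node.age
        span = anc.age - node.age
        k = len(chain) - 1
        for i, n in enumerate(chain[1:-1], start=1):
            n.age = node.age + span * i / k

    tt.sync_edge_lengths()
    _check_positive(tt)
    return tt


def timescale_mbl(
    topology: dendropy.Tree,
    ages: TaxonAges,
    min_length: float = 1.0,
    root_length: float = 1.0,
) -> TimeTree:
    """Date a fossil tree by the minimum-branch-length (mbl) method.

    Tips sit at their FAD; going bottom-up, every parent is pushed back far
    enough that each branch spans at least ``min_length`` myr. If the topology
    already carries node ages satisfying all gaps, they are kept.
    """
    if min_length <= 0:
        raise TreeError("min_length must be positive")
    if root_length <= 0:
        raise TreeError("root_length must be positive")
    tt = _initial_ages(topology, ages)
    # honour pre-existing dated branch lengths if the caller supplied them
    if all(n.edge.length is not None for n in topology.preorder_node_iter()
           if n.parent_node is not None):
        prior = _ages_from_lengths(topology, ages)
        if prior is not None:
            for node, age in zip(tt.tree.preorder_node_iter(), prior):
                node.age = max(node.age, age)
    for node in tt.tree.postorder_node_iter():
        if not node.is_leaf():
            node.age = max(node.age, max(c.age + min_length for c in node.child_nodes()))
    tt.root_length = root_length
    tt.sync_edge_lengths()
    _check_min(tt, min_length)
    return tt


def _ages_from_lengths(topology: dendropy.Tree, ages: TaxonAges) -> list[float] | None:
    """Node ages implied by existing branch lengths, anchored at tip FADs.

    Returns preorder ages, or None if the lengths are inconsistent with a
    single dating (different tips implying different root ages).
    """
    implied: dict[int, float] = {}
    for leaf in topology.leaf_node_iter():
        taxon = leaf.taxon.label
        if taxon not in ages:
            return None
        age = float(ages.fad[taxon])
        node = leaf
        while node is not None:
            implied_age = implied.get(id(node))
            if implied_age is not None and abs(implied_age - age) > 1e-9:
                return None
            implied[id(node)] = age
            if node.parent_node is not None:
                age += node.edge.length
            node = node.parent_node
    return [implied[id(n)] for n in topology.preorder_node_iter()]


def _check_positive(tt: TimeTree) -> None:
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length <= 0:
            raise TreeError(
                f"zero/negative branch above {tt.node_label(node)!r} after scaling"
            )


def _check_min(tt: TimeTree, min_length: float) -> None:
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is not None and node.edge.length < min_length - 1e-9:
            raise TreeError("branch below minimum length after mbl scaling")


# ---------------------------------------------------------------------------
# tree surgery
# ---------------------------------------------------------------------------


def drop_tip(tt: TimeTree, taxon: str) -> TimeTree:
    """Remove one tip, suppressing the resulting degree-2 node.

    Node ages of the remaining nodes are untouched, so branch lengths of
    merged edges add up; used by leave-one-out cross-validation.
    """
    out = tt.copy()
    leaves = {leaf.taxon.label: leaf for leaf in out.tree.leaf_node_iter()}
    if taxon not in leaves:
        raise TreeError(f"tip {taxon!r} not in tree")
    if len(leaves) <= 2:
        raise TreeError("refusing to prune a tree down to a single tip")
    node = leaves[taxon]
    parent = node.parent_node
    parent.remove_child(node)
    if len(parent.child_nodes()) == 1 and parent.parent_node is not None:
        only = parent.child_nodes()[0]
        grand = parent.parent_node
        grand.remove_child(parent)
        grand.add_child(only)
    elif len(parent.child_nodes()) == 1 and parent.parent_node is None:
        # root became unary: its single child is the new root
        only = parent.child_nodes()[0]
        parent.remove_child(only)
        only.parent_node = None
        out.tree.seed_node = only
    out.sync_edge_lengths()
    return out
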