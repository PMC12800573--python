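"""Domain types and file I/O: phylogenies, binary trait matrices, known-pair catalogs.

Strain identifiers are matched by exact string equality after trimming
surrounding whitespace; there is no fuzzy matching.  Trees may be
multifurcating and may contain zero-length branches.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhylolinkError",
    "NewickParseError",
    "ValidationError",
    "Phylogeny",
    "TraitMatrix",
    "KnownPairCatalog",
    "ValidationReport",
    "read_newick",
    "write_newick",
    "read_trait_matrix",
    "write_trait_matrix",
    "read_known_pairs",
    "validate_dataset",
]


class PhylolinkError(Exception):
    """Base class for all phylolink errors."""


class NewickParseError(PhylolinkError):
    """Malformed newick input."""


class ValidationError(PhylolinkError):
    """Input violates a dataset invariant."""


class Phylogeny:
    """Rooted phylogeny with branch lengths, stored as flat parent/child arrays.

    Nodes are integers ``0 .. n_nodes-1``.  ``parent[i]`` is the parent of
    node ``i`` (``-1`` for the root) and ``edge_length[i]`` is the length of
    the branch above node ``i`` (0 for the root).  Tips are nodes without
    children and carry unique, nonempty labels (strain ids).  Multifurcations
    are allowed; branch lengths must be finite and >= 0.
    """

    def __init__(
        self,
        parent: np.ndarray,
        edge_length: np.ndarray,
        labels: list[str | None],
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.labels = list(labels)
        n = self.parent.size
        if not (n == self.edge_length.size == len(self.labels)):
            raise ValidationError("parent, edge_length and labels must have equal length")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots.size}")
        self.root = int(roots[0])
        if not np.all(np.isfinite(self.edge_length)):
            raise ValidationError("branch lengths must be finite")
        if np.any(self.edge_length < 0):
            bad = np.flatnonzero(self.edge_length < 0)
            raise ValidationError(f"negative branch length on node(s) {bad.tolist()}")
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = int(self.parent[i])
            if p >= 0:
                children[p].append(i)
        self.children: tuple[tuple[int, ...], ...] = tuple(tuple(c) for c in children)
        self.tips = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        if self.tips.size < 2:
            raise ValidationError("tree must have at least 2 tips")
        tip_labels = []
        for i in self.tips:
            lab = self.labels[i]
            if lab is None or not str(lab).strip():
                raise ValidationError(f"tip node {i} has no label")
            tip_labels.append(str(lab).strip())
        if len(set(tip_labels)) != len(tip_labels):
            dups = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        self.tip_labels: list[str] = tip_labels
        self.tip_index: dict[str, int] = {lab: int(t) for lab, t in zip(tip_labels, self.tips)}
        self._postorder: np.ndarray | None = None

    # ------------------------------------------------------------------ basics
    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return int(self.tips.size)

    @property
    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=np.int64)
        return self._postorder

    def node_depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        depth = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:  # preorder
            p = self.parent[v]
            if p >= 0:
                depth[v] = depth[p] + self.edge_length[v]
        return depth

    def mean_tip_depth(self) -> float:
        return float(self.node_depths()[self.tips].mean())

    def total_length(self) -> float:
        return float(self.edge_length.sum())

    def rescaled(self, factor: float) -> "Phylogeny":
        """Return a copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValidationError("rescale factor must be > 0")
        return Phylogeny(self.parent.copy(), self.edge_length * factor, list(self.labels))

    # ------------------------------------------------------------- conversion
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        length = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                el = nd.edge.length
                if el is None:
                    raise ValidationError("branch length missing on a non-root edge")
                length[i] = float(el)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise ValidationError("tip without a label")
                labels[i] = str(nd.taxon.label)
        return cls(parent, length, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        def fmt(v: int) -> str:
            if not self.children[v]:
                body = _quote_label(self.labels[v])
            else:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            if v == self.root:
                return body
            return f"{body}:{self.edge_length[v]:.17g}"

        return fmt(self.root) + ";"

    def prune_to(self, keep: set[str]) -> "Phylogeny":
        """Restrict to the given tip labels, suppressing unary nodes.

        Branch lengths of suppressed unary nodes are summed.
        """
        keep = {str(k).strip() for k in keep}
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValidationError(f"tips not in tree: {sorted(missing)}")
        if len(keep) < 2:
            raise ValidationError("cannot prune to fewer than 2 tips")
        alive = np.zeros(self.n_nodes, dtype=bool)
        for lab in keep:
            alive[self.tip_index[lab]] = True
        for v in self.postorder:
            if self.children[v]:
                alive[v] = any(alive[c] for c in self.children[v])
        # rebuild, collapsing unary internal nodes
        new_parent: list[int] = []
        new_length: list[float] = []
        new_labels: list[str | None] = []

        def surviving_children(v: int) -> list[tuple[int, float]]:
            """Alive descendants reached by skipping dead/unary nodes, with path length."""
            out = []
            for c in self.children[v]:
                if not alive[c]:
                    continue
                node, extra = c, self.edge_length[c]
                while True:
                    kids = [k for k in self.children[node] if alive[k]]
                    if len(kids) == 1 and self.labels[node] is None:
                        node = kids[0]
                        extra += self.edge_length[node]
                    else:
                        break
                out.append((node, float(extra)))
            return out

        # find effective root: descend through unary chain
        root = self.root
        while True:
            kids = [k for k in self.children[root] if alive[k]]
            if len(kids) == 1:
                root = kids[0]
            else:
                break

        def build(v: int, parent_idx: int, elen: float) -> None:
            idx = len(new_parent)
            new_parent.append(parent_idx)
            new_length.append(elen)
            new_labels.append(self.labels[v])
            for c, extra in surviving_children(v):
                build(c, idx, extra)

        build(root, -1, 0.0)
        return Phylogeny(np.array(new_parent), np.array(new_length), new_labels)

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes} nodes>"


def _quote_label(label: str | None) -> str:
    lab = "" if label is None else str(label)
    if any(ch in lab for ch in "(),:;[] \t'"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


# ---------------------------------------------------------------------- matrix


class TraitMatrix:
    """Binary strains x traits incidence matrix tagged with a trait kind.

    ``data`` is a pandas DataFrame with strain ids as index and trait ids as
    columns, values strictly in {0, 1}.  ``kind`` is "GCF" or "MF".
    """

    KINDS = ("GCF", "MF")

    def __init__(self, data: pd.DataFrame, kind: str) -> None:
        if kind not in self.KINDS:
            raise ValidationError(f"kind must be one of {self.KINDS}, got {kind!r}")
        data = data.copy()
        data.index = data.index.map(lambda s: str(s).strip())
        data.columns = data.columns.map(lambda s: str(s).strip())
        if data.index.has_duplicates:
            dups = sorted(data.index[data.index.duplicated()].unique())
            raise ValidationError(f"duplicate strain ids: {dups}")
        if data.columns.has_duplicates:
            dups = sorted(data.columns[data.columns.duplicated()].unique())
            raise ValidationError(f"duplicate trait ids: {dups}")
        arr = data.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValidationError(
                f"non-binary cell at strain {data.index[r]!r}, trait {data.columns[c]!r}: "
                f"{arr[r, c]!r}"
            )
        self.data = data.astype(np.int8)
        self.kind = kind

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, trait: str) -> np.ndarray:
        return self.data[trait].to_numpy()

    def reindex_strains(self, order: list[str]) -> "TraitMatrix":
        missing = set(order) - set(self.data.index)
        if missing:
            raise ValidationError(f"strains not in matrix: {sorted(missing)}")
        return TraitMatrix(self.data.loc[order], self.kind)

    def subset_strains(self, keep: set[str]) -> "TraitMatrix":
        keep_order = [s for s in self.data.index if s in keep]
        return TraitMatrix(self.data.loc[keep_order], self.kind)

    def __repr__(self) -> str:
        return f"<TraitMatrix kind={self.kind}: {self.shape[0]} strains x {self.shape[1]} traits>"


@dataclass(frozen=True)
class KnownPairCatalog:
    """Catalog of compounds with known cognate (GCF, MF) pairs."""

    records: pd.DataFrame  # columns: compound, gcf_id, mf_id

    def __post_init__(self) -> None:
        required = {"compound", "gcf_id", "mf_id"}
        if not required.issubset(self.records.columns):
            raise ValidationError(f"catalog requires columns {sorted(required)}")
        if self.records["compound"].duplicated().any():
            dups = sorted(self.records.loc[self.records["compound"].duplicated(), "compound"])
            raise ValidationError(f"duplicate compound names: {dups}")

    def resolve(self, gcf: TraitMatrix, mf: TraitMatrix) -> None:
        """Raise unless every catalog id exists in the matrices."""
        bad_g = sorted(set(self.records["gcf_id"]) - set(gcf.traits))
        bad_m = sorted(set(self.records["mf_id"]) - set(mf.traits))
        if bad_g or bad_m:
            raise ValidationError(f"unresolved catalog ids: GCFs {bad_g}, MFs {bad_m}")

    def __len__(self) -> int:
        return len(self.records)


# -------------------------------------------------------------------- file I/O


def read_newick(path) -> Phylogeny:
    """Read one rooted newick tree (branch lengths required)."""
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.to_newick() + "\n")


def read_trait_matrix(path, kind: str) -> TraitMatrix:
    """Read a tab-separated binary matrix: first column strain id, header trait ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"non-numeric cell in {path}: {exc}") from exc
    return TraitMatrix(df, kind)


def write_trait_matrix(matrix: TraitMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="strain_id")


def read_known_pairs(path) -> KnownPairCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in df.columns:
        df[col] = df[col].str.strip()
    return KnownPairCatalog(df)


# ------------------------------------------------------------------ validation


@dataclass
class ValidationReport:
    """Record of strain-set agreement between a tree and trait matrices."""

    tree_tips: list[str]
    missing_from_tree: dict[str, list[str]] = field(default_factory=dict)
    missing_from_matrix: dict[str, list[str]] = field(default_factory=dict)
    pruned_to: list[str] | None = None

    @property
    def ok(self) -> bool:
        return not any(self.missing_from_tree.values()) and not any(
            self.missing_from_matrix.values()
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_tree_tips": len(self.tree_tips),
                "missing_from_tree": self.missing_from_tree,
                "missing_from_matrix": self.missing_from_matrix,
                "pruned_to": self.pruned_to,
                "ok": self.ok,
            },
            indent=2,
        )


def validate_dataset(
    tree: Phylogeny,
    *matrices: TraitMatrix,
    mode: str = "strict",
) -> tuple[ValidationReport, Phylogeny, list[TraitMatrix]]:
    """Check strain-set agreement between the tree and every matrix.

    In ``strict`` mode any mismatch raises.  In ``prune`` mode the tree and
    all matrices are symmetrically reduced to the intersection of their
    strain sets, and the report records what was dropped.
    """
    if mode not in ("strict", "prune"):
        raise ValueError(f"mode must be 'strict' or 'prune', got {mode!r}")
    tips = set(tree.tip_labels)
    report = ValidationReport(tree_tips=sorted(tips))
    shared = set(tips)
    for i, m in enumerate(matrices):
        name = f"matrix{i}_{m.kind}"
        strains = set(m.strains)
        report.missing_from_tree[name] = sorted(strains - tips)
        report.missing_from_matrix[name] = sorted(tips - strains)
        shared &= strains
    if mode == "strict":
        if not report.ok:
            offenders = sorted(
                set().union(*report.missing_from_tree.values())
                | set().union(*report.missing_from_matrix.values())
            )
            raise ValidationError(f"strain sets disagree; offending ids: {offenders}")
        return report, tree, list(matrices)
    # prune mode
    if len(shared) < 2:
        raise ValidationError("fewer than 2 shared strains after pruning")
    report.pruned_to = sorted(shared)
    new_tree = tree if shared == tips else tree.prune_to(shared)
    new_matrices = [m.subset_strains(shared) for m in matrices]
    return report, new_tree, new_matrices
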