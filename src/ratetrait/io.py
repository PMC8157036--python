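"""Species trees, gene-tree branch-length matrices and trait tables.

The unit of observation throughout the package is the *branch* of the rooted
species tree, not the node: rate fluctuations, trait values and ancestral
predictions are all attached to branches.  Every non-root edge is a branch.
Terminal branches are identified by their leaf label; internal branches by a
short hash of their sorted descendant leaf set, so identifiers are a pure
function of the topology and stable under newick rotation.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "NA"

__all__ = [
    "SpeciesTree",
    "GeneBranchMatrix",
    "TraitTable",
    "TreeFormatError",
    "read_species_tree",
    "read_gene_trees",
    "read_trait_table",
    "write_matrix",
    "read_matrix",
    "write_trait_table",
]


class TreeFormatError(ValueError):
    """Raised when an input tree violates the format contract."""


def _clade_id(leafset: frozenset[str]) -> str:
    """Deterministic identifier for an internal branch from its leaf set."""
    key = "|".join(sorted(leafset)).encode("utf-8")
    return "c" + hashlib.sha1(key).hexdigest()[:10]


class SpeciesTree:
    """A rooted species tree with canonical branch identifiers.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with unique leaf labels.  The root must be bifurcating.
    time_calibrated : bool
        If True, edge lengths are interpreted as durations in Ma and must be
        present and non-negative on every non-root edge.
    """

    def __init__(self, tree: dendropy.Tree, time_calibrated: bool = False):
        self._tree = tree
        self.time_calibrated = time_calibrated

        leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(leaves)) != len(leaves):
            dupes = sorted({x for x in leaves if leaves.count(x) > 1})
            raise TreeFormatError(f"duplicate leaf labels: {dupes}")
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise TreeFormatError(
                "root has %d children; the tree is unrooted — root it first"
                % len(root.child_nodes())
            )
        self.taxa: list[str] = sorted(leaves)

        # assign branch ids bottom-up; annotate each non-root node
        self._leafset: dict[str, frozenset[str]] = {}
        self._parent: dict[str, str | None] = {}
        self._length: dict[str, float | None] = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                node.leafset = frozenset([node.taxon.label])
            else:
                node.leafset = frozenset().union(
                    *(c.leafset for c in node.child_nodes())
                )
            if node is root:
                node.branch_id = None
                continue
            bid = (
                node.taxon.label
                if node.is_leaf()
                else _clade_id(node.leafset)
            )
            node.branch_id = bid
            self._leafset[bid] = node.leafset
            self._length[bid] = node.edge.length
        self._children: dict[str | None, list[str]] = {None: []}
        for node in tree.preorder_node_iter():
            self._children[node.branch_id] = [
                c.branch_id for c in node.child_nodes()
            ]
            if node is root:
                continue
            self._parent[node.branch_id] = node.parent_node.branch_id

        terminal = sorted(self.taxa)
        internal = sorted(
            (b for b in self._leafset if len(self._leafset[b]) > 1),
            key=lambda b: (len(self._leafset[b]), tuple(sorted(self._leafset[b]))),
        )
        self.branch_ids: list[str] = terminal + internal
        self.terminal_branches: list[str] = terminal
        self.internal_branches: list[str] = internal

        if time_calibrated:
            missing = [b for b in self.branch_ids if self._length[b] is None]
            if missing:
                raise TreeFormatError(
                    f"time-calibrated tree lacks durations on branches {missing[:5]}"
                )
            neg = [b for b in self.branch_ids if self._length[b] < 0]
            if neg:
                raise TreeFormatError(f"negative durations on branches {neg[:5]}")

    # -- basic accessors ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, time_calibrated: bool = False) -> "SpeciesTree":
        return cls(_parse_newick(data=newick), time_calibrated=time_calibrated)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def leafset(self, branch_id: str) -> frozenset[str]:
        return self._leafset[branch_id]

    def parent(self, branch_id: str) -> str | None:
        """Branch id of the parent branch (None for children of the root)."""
        return self._parent[branch_id]

    def duration(self, branch_id: str) -> float | None:
        return self._length[branch_id]

    @property
    def durations(self) -> dict[str, float | None]:
        return dict(self._length)

    def root_to_tip_depths(self) -> dict[str, float]:
        depths = {}
        self._tree.seed_node.depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            node.depth = node.parent_node.depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node.depth
        return depths

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = list(self.root_to_tip_depths().values())
        return (max(depths) - min(depths)) <= tol

    def node_ages(self) -> dict[str, float]:
        """Age (Ma before present) of each branch's child node; 0 at tips
        of an ultrametric tree."""
        depths = self.root_to_tip_depths()
        total = max(depths.values())
        ages = {}
        self._tree.seed_node.depth = 0.0
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            node.depth = node.parent_node.depth + (node.edge.length or 0.0)
            ages[node.branch_id] = total - node.depth
        return ages

    def postorder_branches(self) -> list[str]:
        """Branch ids in postorder (children before parents)."""
        out = []
        for node in self._tree.postorder_node_iter():
            if node.parent_node is not None:
                out.append(node.branch_id)
        return out

    def children(self, branch_id: str | None) -> list[str]:
        """Child branch ids of a branch's child node (of the root if None)."""
        return list(self._children[branch_id])

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:
        return f"SpeciesTree(n_taxa={self.n_taxa}, n_branches={len(self.branch_ids)})"


@dataclass
class GeneBranchMatrix:
    """Genes x branches matrix of per-gene branch lengths (substitutions/site).

    ``data`` rows are gene ids, columns are the species tree's branch ids;
    NaN marks a missing entry (taxon absent from that gene's tree).
    """

    data: pd.DataFrame
    n_skipped: int = 0

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("negative branch lengths in gene-branch matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def branches(self) -> list[str]:
        return list(self.data.columns)

    def coverage(self) -> pd.Series:
        """Fraction of non-missing entries per gene."""
        return self.data.notna().mean(axis=1)


@dataclass
class TraitTable:
    """Branches x traits table with per-entry provenance.

    ``values`` rows are branch ids (taxon names for terminal branches),
    columns are trait names.  ``schema`` maps trait name to ``"continuous"``
    (positive real, original scale) or ``"binary"`` (0/1).  ``provenance``
    holds ``observed``/``imputed``/``predicted-ancestral`` for every
    non-missing cell and NaN elsewhere.
    """

    values: pd.DataFrame
    schema: dict[str, str]
    provenance: pd.DataFrame = field(default=None)

    PROVENANCE_LEVELS = ("observed", "imputed", "predicted-ancestral")

    def __post_init__(self):
        if self.provenance is None:
            prov = self.values.copy().astype(object)
            prov[:] = None
            prov[self.values.notna()] = "observed"
            self.provenance = prov
        self.validate()

    def validate(self) -> None:
        unknown = set(self.values.columns) - set(self.schema)
        if unknown:
            raise ValueError(f"traits missing from schema: {sorted(unknown)}")
        for trait, kind in self.schema.items():
            if trait not in self.values.columns:
                continue
            col = self.values[trait].dropna()
            if kind == "continuous":
                bad = col[col <= 0]
                if len(bad):
                    raise ValueError(
                        f"continuous trait {trait!r} has non-positive values "
                        f"for rows {list(bad.index[:5])}"
                    )
            elif kind == "binary":
                if not col.isin([0, 1, 0.0, 1.0]).all():
                    raise ValueError(f"binary trait {trait!r} has values outside {{0,1}}")
            else:
                raise ValueError(f"unknown trait kind {kind!r} for {trait!r}")
        mism = (self.values.notna() != self.provenance.notna()).to_numpy()
        if mism.any():
            raise ValueError("provenance flags do not match non-missing cells")

    def copy(self) -> "TraitTable":
        return TraitTable(
            self.values.copy(), dict(self.schema), self.provenance.copy()
        )

    def observed_rows(self, trait: str) -> list[str]:
        m = self.values[trait].notna() & (self.provenance[trait] == "observed")
        return list(self.values.index[m])


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _parse_newick(**source) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **source
        )
    except dendropy.utility.error.DataParseError as exc:
        raise TreeFormatError(f"newick parse failed: {exc}") from exc


def read_species_tree(path: str | Path, time_calibrated: bool = False) -> SpeciesTree:
    """Read a single rooted newick tree and assign canonical branch ids."""
    return SpeciesTree(_parse_newick(path=str(path)), time_calibrated=time_calibrated)


def _tree_clades(tree: dendropy.Tree) -> dict[frozenset[str], float | None]:
    """Map each non-root edge's descendant leaf set to its branch length."""
    out = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.leafset = frozenset([node.taxon.label])
        else:
            node.leafset = frozenset().union(*(c.leafset for c in node.child_nodes()))
        if node.parent_node is not None:
            out[node.leafset] = node.edge.length
    return out


def read_gene_trees(
    path: str | Path,
    species: SpeciesTree,
    min_coverage: float = 0.8,
) -> GeneBranchMatrix:
    """Map a multi-newick file of gene trees onto species-tree branches.

    Each gene tree must cover a subset of the species taxa with a topology
    concordant with the species tree restricted to those taxa; discordant
    genes are skipped with a warning.  When a gene tree lacks taxa, each
    gene-tree branch is assigned to the lowest species-tree branch whose
    leaf set, restricted to the gene's taxa, matches; species branches left
    unassigned are missing for that gene.  Genes whose resulting row has
    fewer than ``min_coverage`` non-missing entries are dropped.
    """
    trees = dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    rows, names = [], []
    n_skipped = 0
    species_taxa = set(species.taxa)
    branch_leafsets = {b: species.leafset(b) for b in species.branch_ids}

    for i, gt in enumerate(trees):
        gene = gt.label or f"gene_{i + 1:04d}"
        taxa = {lf.taxon.label for lf in gt.leaf_node_iter()}
        if not taxa <= species_taxa:
            logger.warning("gene %s has taxa outside the species tree; skipped", gene)
            n_skipped += 1
            continue
        clades = _tree_clades(gt)
        restricted = {
            b: ls & taxa
            for b, ls in branch_leafsets.items()
            if ls & taxa and ls & taxa != taxa
        }
        # topology concordance: gene clades == distinct proper restrictions
        if set(clades) != set(restricted.values()):
            logger.warning("gene %s topology conflicts with species tree; skipped", gene)
            n_skipped += 1
            continue
        row = {b: np.nan for b in species.branch_ids}
        for clade, length in clades.items():
            cands = [b for b, r in restricted.items() if r == clade]
            target = min(cands, key=lambda b: len(branch_leafsets[b]))
            row[target] = np.nan if length is None else float(length)
        rows.append(row)
        names.append(gene)

    if not rows:
        raise ValueError("no gene trees retained after topology filtering")
    data = pd.DataFrame(rows, index=names, columns=species.branch_ids)
    keep = data.notna().mean(axis=1) >= min_coverage
    n_low = int((~keep).sum())
    if n_low:
        logger.warning("%d genes dropped for coverage < %.2f", n_low, min_coverage)
    data = data.loc[keep]
    if data.empty:
        raise ValueError("no gene trees retained after coverage filtering")
    return GeneBranchMatrix(data, n_skipped=n_skipped + n_low)


def read_trait_table(path: str | Path, schema: dict[str, str]) -> TraitTable:
    """Read a TSV trait table (first column = taxon / branch id).

    Blank cells and ``NA`` are missing.  ``<trait>.provenance`` companion
    columns, as written by :func:`write_trait_table`, are honored; otherwise
    every non-missing entry is flagged ``observed``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""])
    df.index.name = None
    prov_cols = [c for c in df.columns if c.endswith(".provenance")]
    value_cols = [c for c in df.columns if c not in prov_cols]
    values = df[value_cols].astype(float)
    provenance = None
    if prov_cols:
        provenance = pd.DataFrame(index=df.index, columns=value_cols, dtype=object)
        for c in value_cols:
            pc = f"{c}.provenance"
            provenance[c] = df[pc] if pc in df.columns else None
            provenance.loc[values[c].notna() & provenance[c].isna(), c] = "observed"
        provenance[values.isna()] = None
    return TraitTable(values, schema, provenance)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_matrix(M: GeneBranchMatrix, path: str | Path) -> None:
    if M.data.empty:
        raise ValueError("refusing to write an empty gene-branch matrix")
    M.data.to_csv(path, sep="\t", na_rep=MISSING, index_label="gene")


def read_matrix(path: str | Path, species: SpeciesTree | None = None) -> GeneBranchMatrix:
    data = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""])
    data.index.name = None
    if species is not None and set(data.columns) != set(species.branch_ids):
        raise ValueError("matrix columns do not match species-tree branches")
    return GeneBranchMatrix(data)


def write_trait_table(T: TraitTable, path: str | Path) -> None:
    if T.values.empty:
        raise ValueError("refusing to write an empty trait table")
    out = pd.DataFrame(index=T.values.index)
    for c in T.values.columns:
        out[c] = T.values[c]
        out[f"{c}.provenance"] = T.provenance[c]
    out.to_csv(path, sep="\t", na_rep=MISSING, index_label="branch")
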