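"""Newick and PUT-list I/O, plus distance-matrix writers.

Parsing is delegated to :mod:`dendropy`; this module converts to and from
the package's own :class:`~phyloexpand.tree_model.TreeNode` /
:class:`~phyloexpand.tree_model.IndexedTree` representations and enforces
the package's dialect decisions: quoted labels supported, underscores kept
verbatim (no underscore-to-space translation), bracket comments skipped,
child order preserved.

The PUT (phylogenetically uncertain taxon) list is a plain-text format:
one ``species-name MDCC-label`` pair per line, whitespace-separated, with
``#`` comment lines and blank lines ignored.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

from .errors import MdccResolutionError, PutFileError, TreeFormatError
from .tree_model import IndexedTree, PutEntry, TreeNode

__all__ = [
    "PutFile",
    "read_newick",
    "write_newick",
    "read_put_file",
    "resolve_mdccs",
    "write_distance_matrix",
    "auto_label_internal",
]


def _from_dendropy(dnode: dendropy.Node) -> TreeNode:
    """Convert a dendropy subtree into the package's mutable node type."""
    def make(dn):
        label = dn.taxon.label if dn.taxon is not None else dn.label
        return TreeNode(label=label, length=dn.edge.length)

    root = make(dnode)
    stack = [(dnode, root)]
    while stack:
        dn, node = stack.pop()
        for dchild in dn.child_nodes():
            child = node.add_child(make(dchild))
            stack.append((dchild, child))
    return root


def read_newick(stream, *, auto_label: bool = False) -> list[TreeNode]:
    """Read one or more rooted trees from Newick text.

    Parameters
    ----------
    stream:
        Text, or a file-like object with ``read()``.  Each semicolon-
        terminated statement yields one tree.
    auto_label:
        Assign each unlabeled internal node its preorder rank (as a string)
        so that every clade can be addressed as an MDCC.

    Returns a list of :class:`TreeNode` roots, in file order.

    Raises :class:`TreeFormatError` on malformed input (unbalanced
    parentheses, missing terminal ``;``, duplicate leaf labels are caught
    later at indexing time).
    """
    text = stream.read() if hasattr(stream, "read") else stream
    stripped = text.strip()
    if not stripped:
        raise TreeFormatError("empty Newick input")
    if not stripped.endswith(";"):
        raise TreeFormatError(
            f"missing terminal ';' at end of Newick input (near {stripped[-20:]!r})"
        )
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise TreeFormatError(f"Newick parse error: {exc}") from exc
    if not tree_list:
        raise TreeFormatError("no trees found in Newick input")
    roots = [_from_dendropy(t.seed_node) for t in tree_list]
    if auto_label:
        for root in roots:
            auto_label_internal(root)
    return roots


def auto_label_internal(root: TreeNode) -> TreeNode:
    """Label every unlabeled internal node with its preorder rank.

    Raises :class:`TreeFormatError` if a generated label collides with an
    existing one.
    """
    existing = {n.label for n in root.preorder() if n.label}
    for rank, node in enumerate(root.preorder(), start=1):
        if node.children and not node.label:
            label = str(rank)
            if label in existing:
                raise TreeFormatError(
                    f"auto-label {label!r} collides with an existing node label"
                )
            node.label = label
            existing.add(label)
    return root


_NEWICK_UNSAFE = set(" \t\n()[]':;,")


def _format_label(label: str | None) -> str:
    if not label:
        return ""
    if any(ch in _NEWICK_UNSAFE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: float | None, precision: int | None) -> str:
    if length is None:
        return ""
    if precision is None:
        return f":{length!r}"  # shortest representation that round-trips exactly
    return f":{length:.{precision}g}"


def write_newick(t: IndexedTree | TreeNode, *, precision: int | None = None) -> str:
    """Serialise a tree to a single Newick statement (';'-terminated).

    With ``precision=None`` branch lengths are written with Python's
    shortest-round-trip float formatting, so a write/read cycle reproduces
    lengths bit-faithfully.
    """
    root = t.to_tree_node() if isinstance(t, IndexedTree) else t

    out = io.StringIO()
    # explicit stack: trees from large simulations overflow Python recursion
    stack: list = [(root, False)]
    while stack:
        node, visited = stack.pop()
        if node is None:  # separator marker
            out.write(",")
            continue
        if visited:
            out.write(")")
            out.write(_format_label(node.label))
            if node.parent is not None:
                out.write(_format_length(node.length, precision))
            continue
        if node.is_leaf():
            out.write(_format_label(node.label))
            if node.parent is not None:
                out.write(_format_length(node.length, precision))
        else:
            out.write("(")
            stack.append((node, True))
            rev = list(node.children)[::-1]
            for i, child in enumerate(rev):
                stack.append((child, False))
                if i < len(rev) - 1:
                    stack.append((None, False))
    out.write(";")
    return out.getvalue()


@dataclass
class PutFile:
    """Parsed PUT list: ordered entries plus their source line numbers."""

    entries: list[PutEntry] = field(default_factory=list)
    line_numbers: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)


def read_put_file(stream) -> PutFile:
    """Parse a PUT list: one ``species MDCC`` pair per non-blank, non-# line.

    Raises :class:`PutFileError` with the offending line number on lines
    that do not split into exactly two tokens, and on duplicate species.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    put_file = PutFile()
    seen: set = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 2:
            raise PutFileError(
                f"line {lineno}: expected 'species-name MDCC-label', got {len(tokens)} token(s): {raw!r}"
            )
        species, mdcc = tokens
        if species in seen:
            raise PutFileError(f"line {lineno}: duplicate species {species!r}")
        seen.add(species)
        put_file.entries.append(PutEntry(species_name=species, mdcc_label=mdcc))
        put_file.line_numbers.append(lineno)
    return put_file


def resolve_mdccs(put_file: PutFile, t: IndexedTree) -> list[PutEntry]:
    """Bind each entry's MDCC label to a node rank of ``t``.

    Any node label (internal or leaf) may serve as an MDCC; a leaf MDCC
    confines the insertion to that leaf's own branch.  All unmatched labels
    are reported together.  A PUT whose species name is already a leaf of
    the tree is rejected.
    """
    index = t.label_index()
    leaf_labels = {t.labels[u] for u in t.leaves()}
    unmatched = []
    bound = []
    for entry, lineno in zip(put_file.entries, put_file.line_numbers):
        if entry.species_name in leaf_labels:
            raise MdccResolutionError(
                f"line {lineno}: species {entry.species_name!r} is already a leaf of the tree"
            )
        rank = index.get(entry.mdcc_label)
        if rank is None:
            unmatched.append(entry.mdcc_label)
        else:
            bound.append(PutEntry(entry.species_name, entry.mdcc_label, mdcc_node=rank))
    if unmatched:
        raise MdccResolutionError(
            "MDCC label(s) not found in tree: " + ", ".join(repr(x) for x in unmatched)
        )
    return bound


def write_distance_matrix(d, format: str = "phylip-square", *, precision: int = 6) -> str:
    """Render a labeled distance matrix as text.

    ``phylip-square``: first line is the taxon count, then one row per
    taxon (name, then all values).  ``tsv``: header row of labels, then
    one labeled row per taxon.  Values use ``precision`` significant
    digits (default 6).
    """
    labels = d.labels
    values = d.values
    fmt = f"{{:.{precision}g}}"
    rows = []
    if format == "phylip-square":
        rows.append(str(len(labels)))
        for lab, row in zip(labels, values):
            rows.append(f"{lab:<10}  " + "  ".join(fmt.format(v) for v in row))
    elif format == "tsv":
        rows.append("\t".join([""] + list(labels)))
        for lab, row in zip(labels, values):
            rows.append("\t".join([lab] + [fmt.format(v) for v in row]))
    else:
        raise ValueError(f"unknown matrix format {format!r}")
    return "\n".join(rows) + "\n"
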