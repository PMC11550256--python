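"""Reading and writing networks: extended Newick and edge-list formats.

Extended Newick (eNewick) dialect
---------------------------------
Reticulations are written with hybrid tags ``#Hk``: the hybrid node appears
exactly once with its subtree, ``(subtree)#Hk``, and one or more further
times as a bare reference ``#Hk``; every occurrence of the same tag denotes
the same node.  Internal node labels are optional, branch lengths
(``:0.1``) are parsed and ignored, and the description ends with ``;``.

Edge-list format
----------------
TSV with one ``parent<TAB>child`` line per edge, ``#``-comment lines, and
companion leaf-label lines ``L<TAB>node<TAB>label``.  Node identifiers are
arbitrary tokens (numeric or not) and are preserved verbatim as display
names; internally nodes are renumbered to opaque integers.
"""

from __future__ import annotations

import os
from pathlib import Path

from .network import NetworkError, PhyloNetwork

__all__ = [
    "ParseError",
    "parse_enewick",
    "parse_edgelist",
    "write_enewick",
    "write_edgelist",
    "read_network",
    "write_network",
]


def _sorted_nodes(nodes):
    try:
        return sorted(nodes)
    except TypeError:
        return sorted(nodes, key=repr)


class ParseError(NetworkError):
    """Malformed input; carries a 1-based character position."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


# -- eNewick -----------------------------------------------------------------

_NAME_STOP = set("(),;:#\t\n\r ")


class _ENewickParser:
    def __init__(self, text: str):
        self.text = text
        self.i = 0
        self.next_id = 0
        self.edges: list[tuple[int, int]] = []
        self.names: dict[int, str] = {}
        self.leaf_like: list[int] = []  # nodes written without a subtree
        self.hybrid_ids: dict[str, int] = {}
        self.hybrid_subtree_seen: dict[str, int] = {}
        self.hybrid_count: dict[str, int] = {}

    def error(self, msg: str):
        raise ParseError(msg, self.i + 1)

    def peek(self) -> str:
        return self.text[self.i] if self.i < len(self.text) else ""

    def skip_ws(self):
        while self.i < len(self.text) and self.text[self.i] in " \t\n\r":
            self.i += 1

    def new_node(self) -> int:
        v = self.next_id
        self.next_id += 1
        return v

    def read_name(self) -> str:
        start = self.i
        while self.i < len(self.text) and self.text[self.i] not in _NAME_STOP:
            self.i += 1
        return self.text[start : self.i]

    def read_hybrid_tag(self) -> str:
        # '#' already seen; tag is e.g. H1, LGT2 or plain 1
        self.i += 1
        tag = self.read_name()
        if not tag:
            self.error("empty hybrid tag after '#'")
        return tag

    def skip_length(self):
        if self.peek() == ":":
            self.i += 1
            start = self.i
            while self.i < len(self.text) and (
                self.text[self.i].isdigit() or self.text[self.i] in ".-+eE"
            ):
                self.i += 1
            if self.i == start:
                self.error("expected a branch length after ':'")

    def parse(self) -> PhyloNetwork:
        self.skip_ws()
        root = self.subtree(has_parent=False)
        self.skip_ws()
        if self.peek() != ";":
            self.error("expected ';' at end of description")
        self.i += 1
        self.skip_ws()
        if self.i != len(self.text):
            self.error("trailing characters after ';'")
        for tag, n in self.hybrid_count.items():
            if n < 2:
                self.error(f"hybrid tag #{tag} used only once")
        labels = {}
        g_children = {u: [] for u in range(self.next_id)}
        for u, v in self.edges:
            g_children[u].append(v)
        for v in range(self.next_id):
            if not g_children[v] and v in self.names:
                labels[v] = self.names[v]
        dup = [l for l in set(labels.values()) if sum(1 for x in labels.values() if x == l) > 1]
        if dup:
            raise ParseError(f"duplicate leaf label(s): {sorted(dup)}")
        return PhyloNetwork(
            edges=self.edges,
            leaf_labels=labels,
            root=root,
            nodes=range(self.next_id),
            node_names=dict(self.names),
        )

    def subtree(self, has_parent: bool) -> int:
        """Parse one subtree; return its root node id."""
        self.skip_ws()
        children: list[int] = []
        has_group = self.peek() == "("
        if has_group:
            self.i += 1
            children.append(self.subtree(True))
            self.skip_ws()
            while self.peek() == ",":
                self.i += 1
                children.append(self.subtree(True))
                self.skip_ws()
            if self.peek() != ")":
                self.error("expected ')' or ','")
            self.i += 1
        name = self.read_name()
        tag = None
        if self.peek() == "#":
            tag = self.read_hybrid_tag()
        self.skip_length()

        if tag is not None:
            if tag in self.hybrid_ids:
                v = self.hybrid_ids[tag]
            else:
                v = self.new_node()
                self.hybrid_ids[tag] = v
            self.hybrid_count[tag] = self.hybrid_count.get(tag, 0) + 1
            if has_group:
                if tag in self.hybrid_subtree_seen:
                    self.error(f"hybrid tag #{tag} given a subtree more than once")
                self.hybrid_subtree_seen[tag] = v
            if name:
                self.names[v] = name
        else:
            if not has_group and not name:
                self.error("empty node (no name, no subtree)")
            v = self.new_node()
            if name:
                self.names[v] = name
            if not has_group:
                self.leaf_like.append(v)
        for c in children:
            self.edges.append((v, c))
        return v


def parse_enewick(text: str) -> PhyloNetwork:
    """Parse an extended Newick description into a network."""
    return _ENewickParser(text).parse()


def write_enewick(N: PhyloNetwork) -> str:
    """Serialize to eNewick.

    Each reticulation gets a fresh ``#Hk`` tag; its full subtree is written
    under the first parent encountered in a depth-first traversal from the
    root (children in ascending identifier order) and bare references
    elsewhere.  Unlabeled leaves (reduced networks) fall back to their
    display names.
    """
    g = N.graph
    tags: dict = {}
    expanded: set = set()

    def name_of(v) -> str:
        if g.out_degree(v) == 0:
            return N.display_name(v)
        return N.node_names.get(v, "")

    def render(v) -> str:
        if g.in_degree(v) >= 2:
            if v not in tags:
                tags[v] = f"H{len(tags) + 1}"
            if v in expanded:
                return f"#{tags[v]}"
            expanded.add(v)
            inner = render_children(v)
            return f"{inner}{name_of(v)}#{tags[v]}"
        return f"{render_children(v)}{name_of(v)}"

    def render_children(v) -> str:
        kids = _sorted_nodes(g.successors(v))
        if not kids:
            return ""
        return "(" + ",".join(render(c) for c in kids) + ")"

    return render(N.root) + ";"


# -- edge list ---------------------------------------------------------------


def parse_edgelist(text: str) -> PhyloNetwork:
    """Parse the two-column parent→child TSV (with ``L`` label lines)."""
    ids: dict[str, int] = {}

    def node(tok: str) -> int:
        if tok not in ids:
            ids[tok] = len(ids)
        return ids[tok]

    edges: list[tuple[int, int]] = []
    labels_by_tok: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if parts[0] == "L":
            if len(parts) != 3:
                raise ParseError(f"line {lineno}: label line needs 'L node label'")
            if parts[1] in labels_by_tok and labels_by_tok[parts[1]] != parts[2]:
                raise ParseError(f"line {lineno}: conflicting labels for {parts[1]!r}")
            labels_by_tok[parts[1]] = parts[2]
            continue
        if len(parts) != 2:
            raise ParseError(f"line {lineno}: expected 'parent child'")
        u, v = node(parts[0]), node(parts[1])
        edges.append((u, v))
    if not edges and not labels_by_tok:
        raise ParseError("empty edge list")
    labels = {}
    for tok, lab in labels_by_tok.items():
        if tok not in ids:
            ids[tok] = len(ids)
        labels[ids[tok]] = lab
    dup = [l for l in set(labels.values()) if sum(1 for x in labels.values() if x == l) > 1]
    if dup:
        raise ParseError(f"duplicate leaf label(s): {sorted(dup)}")
    names = {i: tok for tok, i in ids.items()}
    return PhyloNetwork(
        edges=edges, leaf_labels=labels, nodes=range(len(ids)), node_names=names
    )


def write_edgelist(N: PhyloNetwork) -> str:
    """Serialize as parent→child TSV plus ``L`` label lines."""
    g = N.graph

    def tok(v) -> str:
        return N.node_names.get(v, str(v))

    lines = ["# parent\tchild"]
    for u in _sorted_nodes(g.nodes):
        for v in _sorted_nodes(g.successors(u)):
            lines.append(f"{tok(u)}\t{tok(v)}")
    for v in _sorted_nodes(N.leaf_labels):
        lines.append(f"L\t{tok(v)}\t{N.leaf_labels[v]}")
    return "\n".join(lines) + "\n"


# -- front door --------------------------------------------------------------

_PARSERS = {"enewick": parse_enewick, "edgelist": parse_edgelist}
_WRITERS = {"enewick": write_enewick, "edgelist": write_edgelist}


def read_network(source, format: str = "enewick") -> PhyloNetwork:
    """Read a network from a path, an open file, or literal text.

    A ``str`` argument is treated as a filesystem path when a file of that
    name exists, and as literal network text otherwise.
    """
    if format not in _PARSERS:
        raise ValueError(f"unknown format {format!r}")
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    return _PARSERS[format](text)


def write_network(N: PhyloNetwork, format: str = "enewick") -> str:
    """Serialize a network to text in the given format."""
    if format not in _WRITERS:
        raise ValueError(f"unknown format {format!r}")
    return _WRITERS[format](N)
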