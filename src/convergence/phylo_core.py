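"""Rooted phylogenies, condition labelling, codon/amino-acid alignments.

A phylogeny is stored in flat arrays indexed by node id (preorder, root = 0).
Branches are identified with their child node, so every node except the root
carries exactly one branch. Condition labels ("ancestral" vs "convergent")
and transition flags live on branches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
GAP = -1

ANCESTRAL = "ancestral"
CONVERGENT = "convergent"


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

class GeneticCode:
    """The standard genetic code restricted to its 61 sense codons.

    Stop codons are excluded from the state space; encountering one in data
    is an error, never a silent gap.
    """

    def __init__(self) -> None:
        table = CodonTable.unambiguous_dna_by_id[1]
        self.stop_codons = set(table.stop_codons)
        self.codons: list[str] = sorted(table.forward_table)
        if len(self.codons) != 61:  # pragma: no cover - standard code
            raise AssertionError("expected 61 sense codons")
        self.codon_index = {c: i for i, c in enumerate(self.codons)}
        self.aa_of_codon = np.array(
            [AA_INDEX[table.forward_table[c]] for c in self.codons], dtype=int
        )

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    def translate_codon(self, codon: str) -> str:
        if codon in self.stop_codons:
            raise ValueError(f"stop codon {codon!r} has no amino-acid state")
        return AA_ORDER[self.aa_of_codon[self.codon_index[codon]]]

    def degeneracy(self) -> np.ndarray:
        """Number of sense codons per amino acid (length 20)."""
        return np.bincount(self.aa_of_codon, minlength=20)


STANDARD_CODE = GeneticCode()


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """Rooted tree in flat-array form.

    ``parent[i]`` is the parent id of node ``i`` (-1 for the root),
    ``lengths[i]`` is the length of the branch entering ``i`` (0 for the
    root), ``names[i]`` is the taxon/node label or None. Branch lengths are
    expected substitutions per site.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str | None]
    children: list[list[int]]

    root: int = 0

    def __post_init__(self) -> None:
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be non-negative")
        leaves = self.leaf_names()
        if len(set(leaves)) != len(leaves):
            raise ValueError("leaf names must be distinct")

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def leaf_names(self) -> list[str]:
        return [self.names[i] or f"node{i}" for i in self.leaves()]

    def node_by_name(self, name: str) -> int:
        for i, n in enumerate(self.names):
            if n == name:
                return i
        raise KeyError(f"no node named {name!r}")

    def preorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        return order

    def postorder(self) -> list[int]:
        return self.preorder()[::-1]

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        v = self.parent[b]
        while v != -1:
            if v == a:
                return True
            v = self.parent[v]
        return False

    def subtree(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            out.append(u)
            stack.extend(self.children[u])
        return out

    def mrca(self, leaf_names: list[str]) -> int:
        ids = [self.node_by_name(n) for n in leaf_names]
        paths = []
        for i in ids:
            p = [i]
            while self.parent[p[-1]] != -1:
                p.append(self.parent[p[-1]])
            paths.append(set(p))
        common = set.intersection(*paths)
        # deepest common ancestor = the one none of whose children is common
        v = self.root
        while True:
            nxt = [c for c in self.children[v] if c in common]
            if not nxt:
                return v
            v = nxt[0]

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.lengths[v]
        return float(depth[self.leaves()].max())

    def newick(self, exclude: set[int] | None = None) -> str:
        """Newick string; ``exclude`` drops whole subtrees (unifurcations
        created by the removal are suppressed, lengths summed)."""
        exclude = exclude or set()

        def rec(v: int) -> str | None:
            kept = [s for c in self.children[v] if c not in exclude
                    for s in [rec(c)] if s is not None]
            label = self.names[v] or ""
            if self.is_leaf(v):
                return f"{label}:{self.lengths[v]:.10g}"
            if not kept:
                return None
            if len(kept) == 1 and v != self.root:
                # suppress unifurcation: absorb this branch into the child
                sub, length = kept[0].rsplit(":", 1)
                return f"{sub}:{float(length) + self.lengths[v]:.10g}"
            inner = ",".join(kept)
            if v == self.root:
                return f"({inner}){label};"
            return f"({inner}){label}:{self.lengths[v]:.10g}"

        s = rec(self.root)
        if s is None or not s.endswith(";"):
            raise ValueError("tree reduced to nothing or a single lineage")
        return s


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    lengths = np.zeros(len(nodes))
    names: list[str | None] = [None] * len(nodes)
    children: list[list[int]] = [[] for _ in nodes]
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            p = index[id(n.parent_node)]
            parent[i] = p
            children[p].append(i)
            lengths[i] = n.edge.length if n.edge.length is not None else 0.0
        if n.taxon is not None:
            names[i] = n.taxon.label
        elif n.label:
            names[i] = n.label
    return PhyloTree(parent=parent, lengths=lengths, names=names,
                     children=children, root=0)


def parse_newick(text: str) -> PhyloTree:
    """Parse a rooted Newick string.

    Missing branch lengths default to 0. Malformed input raises ValueError
    carrying the parser's position diagnostics.
    """
    if not text.strip():
        raise ValueError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise ValueError(
            f"unbalanced parentheses: {text.count('(')} '(' vs "
            f"{text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise ValueError(f"malformed Newick: {exc}") from exc
    return _from_dendropy(dtree)


@dataclass
class ConditionedTree:
    """A PhyloTree whose branches carry condition labels.

    ``is_convergent[i]`` / ``is_transition[i]`` refer to the branch entering
    node ``i``. Transition branches (the unique branch entering each declared
    convergent clade root) are themselves labelled convergent.
    """

    tree: PhyloTree
    is_convergent: np.ndarray
    is_transition: np.ndarray
    clade_roots: list[int] = field(default_factory=list)

    @property
    def n_transitions(self) -> int:
        return len(self.clade_roots)

    def branch_condition(self, i: int) -> str:
        return CONVERGENT if self.is_convergent[i] else ANCESTRAL

    def leaf_conditions(self) -> dict[str, str]:
        t = self.tree
        return {t.names[i]: self.branch_condition(i) for i in t.leaves()}

    def convergent_leaf_sets(self) -> list[list[str]]:
        t = self.tree
        return [[t.names[v] for v in t.subtree(r) if t.is_leaf(v)]
                for r in self.clade_roots]


def annotate_conditions(tree: PhyloTree,
                        clade_roots: set[int] | set[str] | list) -> ConditionedTree:
    """Label branches by condition given the convergent clade roots.

    Clade roots may be node ids or node/leaf names. The branch entering each
    clade root is flagged as the phenotype-transition branch and, like every
    branch inside the clade, labelled convergent. Clades may not nest or
    overlap, and the tree root cannot be a clade root (it has no entering
    branch).
    """
    roots: list[int] = []
    for r in clade_roots:
        roots.append(tree.node_by_name(r) if isinstance(r, str) else int(r))
    roots = sorted(set(roots))
    if not roots:
        raise ValueError("at least one convergent clade root is required")
    if tree.root in roots:
        raise ValueError("the tree root cannot be a convergent clade root")
    for a in roots:
        for b in roots:
            if a != b and tree.is_ancestor(a, b):
                raise ValueError(
                    f"nested convergent clades: node {a} is an ancestor of {b}"
                )
    is_conv = np.zeros(tree.n_nodes, dtype=bool)
    is_trans = np.zeros(tree.n_nodes, dtype=bool)
    for r in roots:
        is_trans[r] = True
        for v in tree.subtree(r):
            is_conv[v] = True
    if is_conv[tree.leaves()].all():
        raise ValueError("convergent clades cover every leaf; no ancestral "
                         "taxa remain")
    return ConditionedTree(tree=tree, is_convergent=is_conv,
                           is_transition=is_trans, clade_roots=roots)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Codon or amino-acid alignment as an integer state matrix.

    ``states`` has shape (n_taxa, n_sites); entries index into the 61 sense
    codons or the 20 amino acids (see ``kind``), with -1 for a gap.
    """

    taxa: list[str]
    states: np.ndarray
    kind: str  # "codon" | "aa"

    def __post_init__(self) -> None:
        if self.kind not in ("codon", "aa"):
            raise ValueError(f"unknown alignment kind {self.kind!r}")
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("state matrix does not match taxon list")

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, i: int, code: GeneticCode = STANDARD_CODE) -> str:
        if self.kind == "codon":
            return "".join("---" if s == GAP else code.codons[s]
                           for s in self.states[i])
        return "".join("-" if s == GAP else AA_ORDER[s]
                       for s in self.states[i])

    @classmethod
    def from_sequences(cls, taxa: list[str], seqs: list[str],
                       kind: str | None = None,
                       code: GeneticCode = STANDARD_CODE) -> "Alignment":
        if not seqs:
            raise ValueError("alignment has no sequences")
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences have unequal lengths")
        if kind is None:
            kind = _guess_kind(seqs)
        rows = []
        for name, seq in zip(taxa, seqs):
            seq = seq.upper()
            if kind == "codon":
                if len(seq) % 3:
                    raise ValueError(
                        f"codon sequence length of {name!r} not a multiple of 3")
                row = []
                for k in range(0, len(seq), 3):
                    codon = seq[k:k + 3]
                    if codon == "---":
                        row.append(GAP)
                    elif codon in code.stop_codons:
                        raise ValueError(
                            f"stop codon {codon} in {name!r} at codon site "
                            f"{k // 3}")
                    elif codon in code.codon_index:
                        row.append(code.codon_index[codon])
                    else:
                        raise ValueError(
                            f"invalid codon {codon!r} in {name!r} at codon "
                            f"site {k // 3}")
            else:
                row = []
                for k, ch in enumerate(seq):
                    if ch == "-":
                        row.append(GAP)
                    elif ch in AA_INDEX:
                        row.append(AA_INDEX[ch])
                    else:
                        raise ValueError(
                            f"invalid amino-acid state {ch!r} in {name!r} at "
                            f"site {k}")
            rows.append(row)
        return cls(taxa=list(taxa), states=np.array(rows, dtype=int), kind=kind)


def _guess_kind(seqs: list[str]) -> str:
    letters = set("".join(seqs).upper()) - {"-"}
    if letters <= set("ACGT") and all(len(s) % 3 == 0 for s in seqs):
        return "codon"
    return "aa"


def translate(alignment: Alignment,
              code: GeneticCode = STANDARD_CODE) -> Alignment:
    """Translate a codon alignment column-wise; gaps are preserved."""
    if alignment.kind != "codon":
        raise ValueError("translate expects a codon alignment")
    out = np.full_like(alignment.states, GAP)
    mask = alignment.states != GAP
    out[mask] = code.aa_of_codon[alignment.states[mask]]
    return Alignment(taxa=list(alignment.taxa), states=out, kind="aa")


def read_alignment(path: str, fmt: str | None = None,
                   kind: str | None = None) -> Alignment:
    """Read a FASTA or (relaxed) Phylip alignment.

    ``fmt`` is inferred from the extension when omitted (.phy/.phylip →
    phylip, anything else → fasta).
    """
    if fmt is None:
        fmt = "phylip" if str(path).lower().endswith((".phy", ".phylip")) \
            else "fasta"
    if fmt == "fasta":
        records = list(SeqIO.parse(path, "fasta"))
    elif fmt == "phylip":
        with open(path) as fh:
            records = list(AlignIO.read(fh, "phylip-relaxed"))
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return Alignment.from_sequences([r.id for r in records],
                                    [str(r.seq) for r in records], kind=kind)


def write_alignment(alignment: Alignment, path: str,
                    fmt: str | None = None) -> None:
    if fmt is None:
        fmt = "phylip" if str(path).lower().endswith((".phy", ".phylip")) \
            else "fasta"
    records = [SeqRecord(Seq(alignment.sequence(i)), id=name, description="")
               for i, name in enumerate(alignment.taxa)]
    if fmt == "fasta":
        SeqIO.write(records, path, "fasta")
    elif fmt == "phylip":
        buf = io.StringIO()
        AlignIO.write(MultipleSeqAlignment(records), buf, "phylip-relaxed")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise ValueError(f"unknown alignment format {fmt!r}")
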