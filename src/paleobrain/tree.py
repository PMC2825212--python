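"""Rooted, time-calibrated phylogenies and trait tables.

The tree model is a light array-based structure: nodes are identified by a
stable postorder index (children before parents, root last), every non-root
node carries a branch length in Myr, and node ages are expressed in Ma
before present (extant tips at age 0).  Newick parsing is delegated to
dendropy; everything downstream (covariance construction, fossil grafting,
polytomy resolution) operates on the arrays directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed or validated."""


class TreeError(ValueError):
    """Raised for structurally invalid tree operations."""


@dataclass(frozen=True)
class PhyloCovariance:
    """Phylogenetic variance-covariance matrix.

    ``matrix[i, j]`` is the shared root-to-MRCA path length (Myr) between
    ``taxa[i]`` and ``taxa[j]``; the diagonal holds root-to-tip path lengths.
    """

    taxa: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")
        object.__setattr__(self, "matrix", m)


class Phylogeny:
    """Rooted tree with branch lengths in Myr.

    Parameters
    ----------
    parent : array of int
        Parent index per node, -1 for the root.  Node order must be a
        postorder (every child precedes its parent; root last).
    lengths : array of float
        Branch length (Myr) of the edge above each node; ignored for root.
    labels : sequence of str or None
        Tip labels (required for tips, optional for internal nodes).
    root_age : float, optional
        Age of the root in Ma before present.  Defaults to the tree height,
        which places the deepest tips at age 0.
    """

    def __init__(self, parent, lengths, labels, root_age=None):
        self.parent = np.asarray(parent, dtype=int)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if self.lengths.size != n or len(self.labels) != n:
            raise TreeError("parent/lengths/labels size mismatch")
        if np.sum(self.parent < 0) != 1 or self.parent[n - 1] != -1:
            raise TreeError("exactly one root required, at the last postorder index")
        if np.any(self.parent[:-1] <= np.arange(n - 1)):
            raise TreeError("node order is not a postorder (child must precede parent)")
        if np.any(self.lengths[:-1] < 0):
            raise TreeError("negative branch length")
        self.lengths[n - 1] = 0.0

        self._children = [[] for _ in range(n)]
        for i in range(n - 1):
            self._children[self.parent[i]].append(i)
        self._is_tip = np.array([len(c) == 0 for c in self._children])
        # root-to-node path lengths
        depth = np.zeros(n)
        for i in range(n - 2, -1, -1):
            depth[i] = depth[self.parent[i]] + self.lengths[i]
        self.depths = depth
        self.height = float(depth[self._is_tip].max()) if n > 1 else 0.0
        self.root_age = self.height if root_age is None else float(root_age)
        if self.root_age < self.height - 1e-9:
            raise TreeError("root_age smaller than tree height")
        for i in np.flatnonzero(self._is_tip):
            if self.labels[i] is None:
                raise TreeError(f"tip {i} has no label")
        tl = [self.labels[i] for i in np.flatnonzero(self._is_tip)]
        if len(set(tl)) != len(tl):
            raise TreeError("duplicate tip labels")
        self._tip_index = {self.labels[i]: i for i in np.flatnonzero(self._is_tip)}

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self):
        return self.parent.size

    @property
    def root(self):
        return self.parent.size - 1

    def children(self, node):
        return list(self._children[node])

    def is_tip(self, node):
        return bool(self._is_tip[node])

    @property
    def tips(self):
        """Tip node indices, in postorder."""
        return np.flatnonzero(self._is_tip)

    @property
    def tip_labels(self):
        return [self.labels[i] for i in self.tips]

    @property
    def internal_nodes(self):
        return np.flatnonzero(~self._is_tip)

    @property
    def node_ages(self):
        """Ages in Ma before present: parent age minus branch length."""
        return self.root_age - self.depths

    def tip(self, label):
        try:
            return self._tip_index[label]
        except KeyError:
            raise TreeError(f"unknown taxon {label!r}") from None

    def is_ultrametric(self, tol=1e-9):
        d = self.depths[self.tips]
        return bool(np.ptp(d) <= tol) if d.size else True

    def zero_length_branches(self):
        """Indices of non-root nodes whose subtending branch has length 0."""
        return [i for i in range(self.n_nodes - 1) if self.lengths[i] == 0.0]

    # -- ancestry --------------------------------------------------------
    def ancestors(self, node):
        """Node indices from ``node`` up to and including the root."""
        out = [node]
        while self.parent[out[-1]] >= 0:
            out.append(self.parent[out[-1]])
        return out

    def mrca(self, i, j):
        a = set(self.ancestors(i))
        for n in self.ancestors(j):
            if n in a:
                return n
        raise TreeError("disconnected nodes")  # pragma: no cover

    def mrca_of_labels(self, labels):
        nodes = [self.tip(l) for l in labels]
        m = nodes[0]
        for n in nodes[1:]:
            m = self.mrca(m, n)
        return m

    def clade_tips(self, node):
        """Tip labels descended from ``node`` (the node itself if a tip)."""
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if self._is_tip[n]:
                out.append(self.labels[n])
            else:
                stack.extend(self._children[n])
        return frozenset(out)

    # -- covariance ------------------------------------------------------
    def path_lengths(self, taxa=None):
        """Root-to-tip path lengths (Myr), ordered as ``taxa``."""
        if taxa is None:
            taxa = self.tip_labels
        return np.array([self.depths[self.tip(t)] for t in taxa])

    def vcv(self, taxa=None):
        """Phylogenetic variance-covariance matrix over tips.

        Entry (i, j) is the root-to-MRCA path length; the diagonal holds the
        full root-to-tip path lengths, so an ultrametric tree has a constant
        diagonal and a fossil tip a shorter one.
        """
        if taxa is None:
            taxa = self.tip_labels
        nodes = [self.tip(t) for t in taxa]
        return PhyloCovariance(tuple(taxa), self.node_cov(nodes))

    def node_cov(self, nodes_a, nodes_b=None):
        """Shared-path matrix between two arbitrary node sets."""
        sym = nodes_b is None
        if sym:
            nodes_b = nodes_a
        anc = {n: self.ancestors(n) for n in set(nodes_a) | set(nodes_b)}
        ancset = {n: set(a) for n, a in anc.items()}
        out = np.empty((len(nodes_a), len(nodes_b)))
        for i, a in enumerate(nodes_a):
            for j, b in enumerate(nodes_b):
                if sym and j < i:
                    out[i, j] = out[j, i]
                    continue
                if a == b:
                    out[i, j] = self.depths[a]
                else:
                    sa = ancset[a]
                    m = next(n for n in anc[b] if n in sa)
                    out[i, j] = self.depths[m]
        return out

    # -- editing ---------------------------------------------------------
    def _to_nested(self):
        """Mutable nested representation: node -> [label, length, children]."""
        rec = {}
        for i in range(self.n_nodes):
            rec[i] = [self.labels[i], float(self.lengths[i]),
                      [rec[c] for c in self._children[i]]]
        return rec[self.root]

    @staticmethod
    def _from_nested(root_rec, root_age=None):
        parent, lengths, labels = [], [], []

        def walk(rec):
            ids = [walk(c) for c in rec[2]]
            idx = len(parent)
            parent.append(-1)
            lengths.append(rec[1])
            labels.append(rec[0])
            for c in ids:
                parent[c] = idx
            return idx

        # need a postorder where children precede parents: walk assigns
        # indices postorder already
        walk(root_rec)
        return Phylogeny(parent, lengths, labels, root_age=root_age)

    def resolve_polytomies(self, seed):
        """Resolve multifurcations to bifurcations with zero-length branches.

        Each polytomy is resolved by repeatedly pairing two randomly chosen
        children under a new zero-length internal node, so every pairwise
        covariance (and hence every downstream estimate) is unchanged.
        """
        rng = np.random.default_rng(seed)
        root = self._to_nested()
        stack = [root]
        while stack:
            rec = stack.pop()
            while len(rec[2]) > 2:
                i, j = sorted(rng.choice(len(rec[2]), size=2, replace=False))
                a, b = rec[2][i], rec[2][j]
                rec[2] = [c for k, c in enumerate(rec[2]) if k not in (i, j)]
                rec[2].append([None, 0.0, [a, b]])
            stack.extend(rec[2])
        return Phylogeny._from_nested(root, root_age=self.root_age)

    def graft_fossil(self, at_node, label, last_occurrence):
        """Attach a fossil tip at an existing node.

        The new branch length is ``age(at_node) - last_occurrence`` so the
        fossil tip sits at its last-occurrence age (Ma).  Grafting at a node
        creates/extends a polytomy there, mirroring the minimal-assumption
        placement of fossils whose exact branching position is unknown.
        """
        if isinstance(at_node, str):
            at_node = self.mrca_of_labels(self.clade_tips_by_label(at_node))
        age = float(self.node_ages[at_node])
        if last_occurrence > age + 1e-12:
            raise TreeError(
                f"fossil {label!r} last occurrence {last_occurrence} Ma is older "
                f"than its attachment node (age {age} Ma)")
        blen = max(age - last_occurrence, 0.0)
        root = self._to_nested()
        # locate the record for at_node by parallel postorder walk
        order = []

        def walk(rec):
            for c in rec[2]:
                walk(c)
            order.append(rec)

        walk(root)
        order[at_node][2].append([label, blen, []])
        return Phylogeny._from_nested(root, root_age=self.root_age)

    def clade_tips_by_label(self, internal_label):
        for i in self.internal_nodes:
            if self.labels[i] == internal_label:
                return self.clade_tips(i)
        raise TreeError(f"no internal node labelled {internal_label!r}")

    def drop_tips(self, labels):
        """Prune tips (e.g. fossils), suppressing resulting unifurcations."""
        drop = set(labels)
        missing = drop - set(self.tip_labels)
        if missing:
            raise TreeError(f"unknown tips {sorted(missing)}")
        if drop >= set(self.tip_labels):
            raise TreeError("cannot drop every tip")

        def prune(rec):
            if not rec[2]:
                return None if rec[0] in drop else rec
            kept = [r for r in (prune(c) for c in rec[2]) if r is not None]
            if not kept:
                return None
            if len(kept) == 1:  # suppress unifurcation
                kept[0][1] += rec[1]
                return kept[0]
            rec[2] = kept
            return rec

        root = prune(self._to_nested())
        root[1] = 0.0
        return Phylogeny._from_nested(root, root_age=None)

    # -- newick ----------------------------------------------------------
    def to_newick(self):
        def fmt(rec):
            lbl = rec[0] or ""
            if rec[2]:
                inner = ",".join(fmt(c) for c in rec[2])
                s = f"({inner}){lbl}"
            else:
                s = lbl
            return s if rec is root else f"{s}:{rec[1]:.12g}"

        root = self._to_nested()
        return fmt(root) + ";"

    def __repr__(self):
        return (f"<Phylogeny {len(self.tips)} tips, {self.n_nodes} nodes, "
                f"height {self.height:.3g} Myr>")


def read_newick(text, root_age=None):
    """Parse a Newick string into a :class:`Phylogeny`.

    Parameters
    ----------
    text : str
        Newick with branch lengths on all non-root edges.
    root_age : float, optional
        Calibrated root age in Ma; defaults to the tree height.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=False,
                                  preserve_underscores=True)
    except Exception as e:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {e}") from e
    parent, lengths, labels = [], [], []

    def walk(node):
        ids = [walk(c) for c in node.child_nodes()]
        idx = len(parent)
        parent.append(-1)
        el = node.edge.length
        if el is not None and el < 0:
            raise NewickError(f"negative branch length {el}")
        lengths.append(0.0 if el is None else float(el))
        labels.append(node.taxon.label if node.taxon is not None else
                      (node.label or None))
        for c in ids:
            parent[c] = idx
        return idx

    walk(dtree.seed_node)
    if len(parent) < 2:
        raise NewickError("tree must have at least one branch")
    return Phylogeny(parent, lengths, labels, root_age=root_age)


def read_newick_file(path, root_age=None):
    with open(path) as fh:
        return read_newick(fh.read(), root_age=root_age)


def write_newick(tree, path=None):
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

@dataclass
class TraitTable:
    """Per-taxon log10 brain and body mass with extant/extinct flags.

    ``data`` is indexed by taxon with columns ``log10_brain`` (log10 g),
    ``log10_body`` (log10 g) and ``extant`` (bool).
    """

    data: pd.DataFrame

    def __post_init__(self):
        d = self.data
        required = {"log10_brain", "log10_body", "extant"}
        if not required <= set(d.columns):
            raise ValueError(f"trait table needs columns {sorted(required)}")
        if d.index.duplicated().any():
            raise ValueError("duplicate taxa in trait table")
        if not np.isfinite(d[["log10_brain", "log10_body"]].to_numpy()).all():
            raise ValueError("non-finite trait values")

    @property
    def taxa(self):
        return list(self.data.index)

    @property
    def extant_taxa(self):
        return list(self.data.index[self.data["extant"]])

    @property
    def fossil_taxa(self):
        return list(self.data.index[~self.data["extant"]])

    def values_for(self, taxa, column):
        return self.data.loc[list(taxa), column].to_numpy(dtype=float)

    def subset(self, taxa):
        return TraitTable(self.data.loc[list(taxa)].copy())

    def validate_against(self, tree):
        missing = set(self.taxa) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")

    @classmethod
    def from_masses(cls, taxa, brain_g, body_g, extant):
        brain_g = np.asarray(brain_g, float)
        body_g = np.asarray(body_g, float)
        if np.any(brain_g <= 0) or np.any(body_g <= 0):
            raise ValueError("raw masses must be positive")
        return cls(pd.DataFrame({
            "log10_brain": np.log10(brain_g),
            "log10_body": np.log10(body_g),
            "extant": np.asarray(extant, bool),
        }, index=pd.Index(taxa, name="taxon")))


def read_trait_table(path_or_buf):
    """Read a trait TSV: ``taxon  brain_g  body_g  extant``.

    ``brain_g`` may be replaced by ``cranial_capacity_cc``; volumes are then
    converted to brain mass with the standard primate conversion (see
    :mod:`paleobrain.allometry`).
    """
    from .allometry import brain_mass_from_cranial_capacity

    df = pd.read_csv(path_or_buf, sep="\t")
    if "taxon" not in df.columns:
        raise ValueError("trait table must have a 'taxon' column")
    if "brain_g" not in df.columns:
        if "cranial_capacity_cc" not in df.columns:
            raise ValueError("need brain_g or cranial_capacity_cc column")
        df["brain_g"] = brain_mass_from_cranial_capacity(
            df["cranial_capacity_cc"].to_numpy(float))
    extant = df["extant"]
    if extant.dtype == object:
        extant = extant.astype(str).str.lower().isin({"1", "true", "yes"})
    return TraitTable.from_masses(df["taxon"], df["brain_g"], df["body_g"],
                                  extant.astype(bool))


def write_trait_table(traits, path):
    d = traits.data
    out = pd.DataFrame({
        "taxon": d.index,
        "brain_g": 10.0 ** d["log10_brain"].to_numpy(),
        "body_g": 10.0 ** d["log10_body"].to_numpy(),
        "extant": d["extant"].astype(int).to_numpy(),
    })
    out.to_csv(path, sep="\t", index=False)


def read_fossil_placements(path_or_buf):
    """Fossil placement TSV: ``taxon  attach_node  last_occurrence_ma``.

    ``attach_node`` is a comma-separated list of tip labels whose MRCA is
    the attachment node (or a single internal-node label).
    """
    return pd.read_csv(path_or_buf, sep="\t")


def graft_fossils_from_table(tree, placements):
    out = tree
    for _, row in placements.iterrows():
        spec = str(row["attach_node"])
        if "," in spec:
            node = out.mrca_of_labels([s.strip() for s in spec.split(",")])
        else:
            node = out.tip(spec) if spec in out.tip_labels else \
                out.mrca_of_labels(out.clade_tips_by_label(spec))
        out = out.graft_fossil(node, row["taxon"],
                               float(row["last_occurrence_ma"]))
    return out


def matched_internal_nodes(tree_a, tree_b):
    """Pair internal nodes of two trees by their induced extant-tip clades.

    Used to compare ancestral estimates with and without fossil tips: fossil
    grafting preserves every extant clade, so the MRCA of a shared extant
    tip set identifies "the same" ancestor in both trees.  Returns a list of
    ``(node_a, node_b)`` pairs.
    """
    shared = set(tree_a.tip_labels) & set(tree_b.tip_labels)
    by_clade_b = {}
    for n in tree_b.internal_nodes:
        c = tree_b.clade_tips(n) & shared
        if len(c) >= 2:
            by_clade_b.setdefault(c, n)
    pairs = []
    seen = set()
    for n in tree_a.internal_nodes:
        c = tree_a.clade_tips(n) & shared
        if len(c) >= 2 and c in by_clade_b and c not in seen:
            pairs.append((n, by_clade_b[c]))
            seen.add(c)
    return pairs
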