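"""Fixed lineage-tree topology inference: maximum parsimony with the
germline as outgroup, plus GY94 maximum-likelihood branch refinement.

The supported protocol mirrors common BCR practice: estimate topologies
cheaply (parsimony with stepwise addition and NNI hill-climbing at the
nucleotide level), root each tree at the predicted germline, then
re-estimate branch lengths by ML under GY94 with repertoire-shared
kappa/omega and empirical codon frequencies.  Full ML topology search
under the HLP models is deliberately not offered; parameters are always
estimated on fixed topologies.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .codon_space import NUCLEOTIDES
from .phylo_likelihood import CompiledLineage, LineageData
from .substitution_models import EigenPropagator, ModelParams, build_q_gy94
from .trees import LineageTree, TreeNode

_NT_BIT = {b: 1 << i for i, b in enumerate(NUCLEOTIDES)}


def _encode_nt(seq: str, keep: np.ndarray) -> np.ndarray:
    """Bitmask-encode the nucleotides of scored codon sites (ambiguous
    characters become the full set, i.e. parsimony-uninformative)."""
    bits = []
    for ci in np.flatnonzero(keep):
        for b in seq[3 * ci:3 * ci + 3]:
            bits.append(_NT_BIT.get(b.upper(), 0b1111))
    return np.array(bits, dtype=np.uint8)


def _fitch_score(tree: LineageTree, tipsets: dict[str, np.ndarray],
                 germ: np.ndarray) -> int:
    """Fitch parsimony score of a germline-rooted tree (root state counts:
    the germline is a state-bearing node)."""
    score = 0
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip and node is not tree.root:
            sets[id(node)] = tipsets[node.label]
            continue
        acc = germ if node is tree.root else None
        for c in node.children:
            cs = sets[id(c)]
            if acc is None:
                acc = cs
                continue
            inter = acc & cs
            empty = inter == 0
            score += int(empty.sum())
            acc = np.where(empty, acc | cs, inter)
        sets[id(node)] = acc if acc is not None else germ
    return score


def _fitch_edge_changes(tree: LineageTree, tipsets: dict[str, np.ndarray],
                        germ: np.ndarray) -> dict[int, int]:
    """Per-edge change counts from one Fitch backtrack pass (parent state
    preferred at ties)."""
    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_tip and node is not tree.root:
            down[id(node)] = tipsets[node.label]
            continue
        acc = germ if node is tree.root else None
        for c in node.children:
            cs = down[id(c)]
            if acc is None:
                acc = cs
                continue
            inter = acc & cs
            acc = np.where(inter == 0, acc | cs, inter)
        down[id(node)] = acc if acc is not None else germ

    changes: dict[int, int] = {}
    state: dict[int, np.ndarray] = {}

    def _pick_first(mask: np.ndarray) -> np.ndarray:
        # lowest set bit = deterministic choice among equally parsimonious states
        return mask & (-mask).astype(np.uint8)

    root = tree.root
    state[id(root)] = _pick_first(germ)
    for node in reversed(list(tree.postorder())):
        if node is root:
            continue
        ps = state[id(node.parent)]
        ds = down[id(node)]
        keep = ps & ds
        chosen = np.where(keep != 0, keep, _pick_first(ds))
        changes[id(node)] = int((keep == 0).sum())
        state[id(node)] = chosen
    return changes


def _attachment_edges(tree: LineageTree) -> list[TreeNode]:
    return tree.nonroot_nodes()


def _insert_tip(tree: LineageTree, edge_child: TreeNode, tip: TreeNode) -> TreeNode:
    """Insert ``tip`` on the edge above ``edge_child``; returns the new
    internal node (for undo)."""
    parent = edge_child.parent
    joint = TreeNode(None, 0.0)
    idx = parent.children.index(edge_child)
    parent.children[idx] = joint
    joint.parent = parent
    joint.add_child(edge_child)
    joint.add_child(tip)
    return joint


def _remove_tip(tree: LineageTree, joint: TreeNode, tip: TreeNode) -> None:
    edge_child = next(c for c in joint.children if c is not tip)
    parent = joint.parent
    idx = parent.children.index(joint)
    parent.children[idx] = edge_child
    edge_child.parent = parent


def parsimony_topology(lineage: LineageData, seed: int = 0) -> LineageTree:
    """Heuristic maximum-parsimony topology rooted at the germline.

    Stepwise addition in input order followed by NNI hill-climbing, scored
    at the nucleotide level over non-IGNORED codon sites.  Ties during
    addition are arbitrated deterministically from ``seed``.  Duplicate
    sequences are collapsed to a single tip with multiplicity recorded on
    the lineage.  Initial branch lengths are parsimony changes divided by
    the number of scored codon sites.
    """
    rng = np.random.default_rng(seed)
    keep = lineage.mask.is_scored

    seen: dict[str, str] = {}
    lineage.multiplicity = {}
    labels: list[str] = []
    for sid, seq in lineage.sequences.items():
        if seq in seen:
            lineage.multiplicity[seen[seq]] += 1
        else:
            seen[seq] = sid
            lineage.multiplicity[sid] = 1
            labels.append(sid)

    tipsets = {sid: _encode_nt(lineage.sequences[sid], keep) for sid in labels}
    germ = _encode_nt(lineage.germline, keep)

    root = TreeNode(lineage.tree.germline_label if lineage.tree else "GERMLINE")
    tree = LineageTree(root)
    tree.root.add_child(TreeNode(labels[0], 0.0))
    for lbl in labels[1:]:
        tip = TreeNode(lbl, 0.0)
        best_score, best_edges = None, []
        for edge_child in _attachment_edges(tree):
            joint = _insert_tip(tree, edge_child, tip)
            s = _fitch_score(tree, tipsets, germ)
            _remove_tip(tree, joint, tip)
            if best_score is None or s < best_score:
                best_score, best_edges = s, [edge_child]
            elif s == best_score:
                best_edges.append(edge_child)
        choice = best_edges[rng.integers(len(best_edges))] if len(best_edges) > 1 \
            else best_edges[0]
        _insert_tip(tree, choice, tip)

    _nni_search(tree, lambda t: _fitch_score(t, tipsets, germ))

    n_sites = int(keep.sum())
    changes = _fitch_edge_changes(tree, tipsets, germ)
    for node in tree.nonroot_nodes():
        node.length = changes.get(id(node), 0) / max(n_sites, 1)
    return tree


def _nni_search(tree: LineageTree, score_fn, max_passes: int = 10) -> None:
    """Greedy nearest-neighbor-interchange hill climbing (first
    improvement), repeated until a full pass yields none."""
    for _ in range(max_passes):
        improved = False
        current = score_fn(tree)
        for node in list(tree.postorder()):
            # internal edge: node internal, parent internal non-root
            if node.is_tip or node.parent is None or node.parent is tree.root:
                continue
            parent = node.parent
            siblings = [c for c in parent.children if c is not node]
            if len(siblings) != 1 or len(node.children) != 2:
                continue
            sib = siblings[0]
            for ci in range(2):
                child = node.children[ci]
                pk = parent.children.index(sib)
                # swap child (under node) with sib (under parent)
                node.children[ci], parent.children[pk] = sib, child
                sib.parent, child.parent = node, parent
                s = score_fn(tree)
                if s < current:
                    current = s
                    improved = True
                    break
                # undo
                node.children[ci], parent.children[pk] = child, sib
                sib.parent, child.parent = parent, node
        if not improved:
            break


def gy94_branch_refine(
    lineage: LineageData,
    tree: LineageTree,
    kappa: float,
    omega: float,
    pi: np.ndarray | None = None,
    nni: bool = False,
    maxiter: int = 60,
) -> LineageTree:
    """Re-optimize branch lengths by ML under GY94 with shared kappa/omega
    and empirical codon frequencies; optionally accept NNI moves that
    improve the log-likelihood by more than 1e-4."""
    from .codon_space import empirical_codon_frequencies

    if pi is None:
        pi = empirical_codon_frequencies(list(lineage.sequences.values()) + [lineage.germline])
    params = ModelParams(kappa=kappa, omega_fwr=omega, omega_cdr=omega, pi=pi)
    qf = build_q_gy94(params, "FWR")
    qc = build_q_gy94(params, "CDR")
    pf, pc = EigenPropagator(qf.q), EigenPropagator(qc.q)

    work = lineage.tree
    lineage.tree = tree

    def optimize_blens() -> float:
        clin = CompiledLineage(lineage)
        b0 = np.maximum(clin.branch_lengths(), 1e-4)

        def neg(b):
            return -clin.loglik(pf, pc, b, "germline", pi)

        res = optimize.minimize(neg, b0, method="L-BFGS-B",
                                bounds=[(0.0, 10.0)] * len(b0),
                                options={"maxiter": maxiter, "ftol": 1e-10})
        best = min(res.fun, neg(b0))
        lineage.tree.set_branch_lengths(res.x if res.fun <= neg(b0) else b0)
        return -best

    ll = optimize_blens()
    if nni:
        def nni_score(t: LineageTree) -> float:
            clin = CompiledLineage(lineage)
            return -clin.loglik(pf, pc, np.maximum(clin.branch_lengths(), 1e-4),
                                "germline", pi)

        _nni_search(lineage.tree, nni_score)
        ll = optimize_blens()
    out = lineage.tree
    lineage.tree = work
    return out
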