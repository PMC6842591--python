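"""Repertoire and lineage log-likelihoods by Felsenstein pruning.

The models here are nonreversible and nonstationary, and B-cell lineages
come with a predicted germline ancestor, so by default the root state is
*known*: the partial likelihood at the root is evaluated at the germline
codon of each site, with no frequency term.  An alternative "pi" root mode
(germline attached as a zero-length tip, root partials summed against pi)
exists solely so that AIC values are comparable with reversible-model
conventions.

Per-site partial likelihoods are rescaled at every internal node and the
log of the scaling factor accumulated, so trees with hundreds of tips do
not underflow.  Identical site patterns (same germline codon, same tip
codons, same region) are collapsed and weighted, which is a large saving
on low-diversity B-cell data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_space import CODON_SPACE, RegionMask, seq_to_codon_indices
from .substitution_models import (
    EigenPropagator,
    ModelParams,
    build_q,
    mean_field_context,
)
from .trees import LineageTree

N = CODON_SPACE.n


@dataclass
class LineageData:
    """One clonal lineage: aligned sequences, germline, region mask, tree.

    Sequences are nucleotide strings of equal length (a multiple of 3);
    codons containing gaps/ambiguities are treated as missing data in the
    likelihood, never dropped.
    """

    name: str
    sequences: dict[str, str]
    germline: str
    mask: RegionMask
    tree: LineageTree | None = None
    multiplicity: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()} | {len(self.germline)}
        if len(lengths) != 1:
            raise ValueError(f"lineage {self.name}: unequal alignment lengths {sorted(lengths)}")
        (length,) = lengths
        if length % 3:
            raise ValueError(f"lineage {self.name}: alignment length {length} not divisible by 3")
        if len(self.mask) != length // 3:
            raise ValueError(
                f"lineage {self.name}: mask length {len(self.mask)} != {length // 3} codons")

    @property
    def n_codons(self) -> int:
        return len(self.germline) // 3

    def n_unique_sequences(self) -> int:
        return len(set(self.sequences.values()))


@dataclass
class Repertoire:
    """A collection of lineages sharing one set of substitution parameters."""

    lineages: list[LineageData]
    params: ModelParams | None = None
    model_tag: str = "hlp19"

    def __post_init__(self) -> None:
        if not self.lineages:
            raise ValueError("repertoire must contain at least one lineage")

    def all_sequences(self) -> list[str]:
        return [s for lin in self.lineages for s in lin.sequences.values()]

    def germline_sequences(self) -> list[str]:
        return [lin.germline for lin in self.lineages]

    def mean_root_to_tip(self) -> float:
        vals = [lin.tree.mean_root_to_tip() for lin in self.lineages if lin.tree is not None]
        return float(np.mean(vals)) if vals else 0.0


class CompiledLineage:
    """Site-pattern-compressed view of a lineage used by the pruning core.

    Attributes
    ----------
    germ : (npat,) germline codon index per pattern
    tipcodes : (ntips, npat) codon index per tip (-1 = missing)
    fwr_idx, cdr_idx : pattern indices by region
    counts : pattern multiplicities
    order : traversal plan; list of (node_key, [(child_key, child_is_tip,
        tip_row or None, branch_index)]) in postorder, root last
    """

    def __init__(self, lineage: LineageData):
        if lineage.tree is None:
            raise ValueError(f"lineage {lineage.name} has no tree")
        self.lineage = lineage
        tree = lineage.tree
        tree.resolve_multifurcations()

        tip_labels = tree.tip_labels()
        for lbl in tip_labels:
            if lbl not in lineage.sequences:
                raise ValueError(
                    f"lineage {lineage.name}: tree tip {lbl!r} has no matching sequence")

        germ_all = seq_to_codon_indices(lineage.germline)
        tips_all = np.stack([seq_to_codon_indices(lineage.sequences[l]) for l in tip_labels]) \
            if tip_labels else np.empty((0, len(germ_all)), dtype=np.int64)

        scored = lineage.mask.is_scored & (germ_all >= 0)
        if not scored.any():
            raise ValueError(f"lineage {lineage.name}: no scorable sites")
        is_cdr = lineage.mask.is_cdr[scored]
        germ = germ_all[scored]
        tips = tips_all[:, scored]

        # collapse identical site patterns (germline, tips, region)
        cols = np.vstack([germ, tips, is_cdr.astype(np.int64)])
        _, first, inverse = np.unique(cols.T, axis=0, return_index=True, return_inverse=True)
        self.counts = np.bincount(inverse).astype(float)
        self.germ = germ[first]
        self.tipcodes = tips[:, first]
        pat_cdr = is_cdr[first]
        self.cdr_idx = np.flatnonzero(pat_cdr)
        self.fwr_idx = np.flatnonzero(~pat_cdr)
        self.npat = len(first)
        self.n_scored_sites = int(scored.sum())

        # traversal plan over the current topology
        self.rebuild_traversal()

    def rebuild_traversal(self) -> None:
        tree = self.lineage.tree
        tip_labels = tree.tip_labels()
        tip_row = {lbl: i for i, lbl in enumerate(tip_labels)}
        nonroot = tree.nonroot_nodes()
        branch_index = {id(n): i for i, n in enumerate(nonroot)}
        self.n_branches = len(nonroot)
        self.order = []
        for node in tree.postorder():
            if node.is_tip and node is not tree.root:
                continue
            plan = []
            for c in node.children:
                plan.append((id(c), c.is_tip, tip_row.get(c.label) if c.is_tip else None,
                             branch_index[id(c)]))
            self.order.append((id(node), plan))

    def branch_lengths(self) -> np.ndarray:
        return self.lineage.tree.branch_lengths()

    def loglik(self, prop_fwr, prop_cdr, blens: np.ndarray,
               root_mode: str = "germline", pi: np.ndarray | None = None) -> float:
        """Pruning log-likelihood given per-region propagators P(t)."""
        npat = self.npat
        logscale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}

        def edge_contrib(child_key, is_tip, row, bidx):
            t = float(blens[bidx])
            pf, pc = prop_fwr(t), prop_cdr(t)
            out = np.empty((npat, N))
            if is_tip:
                codes = self.tipcodes[row]
                for idx, p in ((self.fwr_idx, pf), (self.cdr_idx, pc)):
                    if idx.size:
                        c = codes[idx]
                        sub = p[:, np.maximum(c, 0)].T
                        sub[c < 0] = 1.0
                        out[idx] = sub
            else:
                part = partials.pop(child_key)
                if self.fwr_idx.size:
                    out[self.fwr_idx] = part[self.fwr_idx] @ pf.T
                if self.cdr_idx.size:
                    out[self.cdr_idx] = part[self.cdr_idx] @ pc.T
            return out

        for node_key, plan in self.order:
            m = np.ones((npat, N))
            for child in plan:
                m *= edge_contrib(*child)
            if plan:
                top = m.max(axis=1)
                top[top <= 0] = 1.0
                m /= top[:, None]
                logscale += np.log(top)
            partials[node_key] = m

        root_key = self.order[-1][0]
        rootpart = partials[root_key]
        site_lik = rootpart[np.arange(npat), self.germ]
        if root_mode == "pi":
            if pi is None:
                raise ValueError("pi root mode requires a frequency vector")
            site_lik = site_lik * pi[self.germ]
        elif root_mode != "germline":
            raise ValueError(f"unknown root mode {root_mode!r}")
        with np.errstate(divide="ignore"):
            return float(np.dot(self.counts, np.log(site_lik) + logscale))


def _propagators(params: ModelParams, model_tag: str):
    context = None if model_tag.lower() == "gy94" else mean_field_context(pi=params.pi)
    qf = build_q(params, "FWR", model_tag, context)
    qc = build_q(params, "CDR", model_tag, context)
    return EigenPropagator(qf.q), EigenPropagator(qc.q)


def lineage_loglik(lineage: LineageData, params: ModelParams, model_tag: str = "hlp19",
                   root_mode: str = "germline") -> float:
    """Log-likelihood of one lineage under the given model, germline-rooted.

    In the default root mode the germline codon is the known root state.
    """
    clin = CompiledLineage(lineage)
    pf, pc = _propagators(params, model_tag)
    return clin.loglik(pf, pc, clin.branch_lengths(), root_mode=root_mode, pi=params.pi)


def root_frequency_mode_loglik(lineage: LineageData, params: ModelParams,
                               model_tag: str = "hlp19") -> float:
    """Likelihood with the germline as a zero-length tip and root partials
    summed against pi; used only for cross-model AIC comparability."""
    return lineage_loglik(lineage, params, model_tag, root_mode="pi")


def repertoire_loglik(rep: Repertoire, params: ModelParams | None = None,
                      model_tag: str | None = None, root_mode: str = "germline") -> float:
    """Sum of lineage log-likelihoods under shared parameters (lineages are
    assumed to mutate independently)."""
    params = params if params is not None else rep.params
    model_tag = model_tag if model_tag is not None else rep.model_tag
    if params is None:
        raise ValueError("no parameters supplied")
    pf, pc = _propagators(params, model_tag)
    total = 0.0
    for lin in rep.lineages:
        try:
            clin = CompiledLineage(lin)
            total += clin.loglik(pf, pc, clin.branch_lengths(), root_mode=root_mode,
                                 pi=params.pi)
        except Exception as exc:
            raise RuntimeError(f"likelihood failed for lineage {lin.name}: {exc}") from exc
    return total
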