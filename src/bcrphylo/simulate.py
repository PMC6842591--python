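"""Synthetic B-cell repertoire generation.

The generator emulates the structural features of blood-derived BCR
repertoires that matter for repertoire-wide inference: many small clones
with a power-law size distribution (~92% singletons under the defaults),
a germline ancestor per clone, FWR/CDR codon partitions with an excluded
(IGNORED) CDR3 block, and sequences evolved along coalescent lineage trees
under context-sensitive somatic hypermutation.

Two sequence evolvers are provided.  ``evolve_hlp19_full_context`` is an
exact stochastic (Gillespie) simulation of the HLP19 process in which
motif hot/cold spots are evaluated on the *actual* flanking bases of the
current sequence -- deliberately richer than the mean-field estimator, so
simulation/refit round trips probe the estimator under realistic model
mismatch.  ``evolve_s5f`` uses a 5-mer mutability/substitution table in
the style of empirical SHM targeting models.  Both forbid substitutions
that would create stop codons.

Branch lengths are interpreted as expected substitutions per codon under
the h=0 rate normalization evaluated at the clone's germline composition.
"""

from __future__ import annotations

import itertools
import json
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np

from .codon_space import (
    CODON_SPACE,
    IUPAC,
    MOTIF_NAMES,
    MOTIFS,
    NUCLEOTIDES,
    CDR,
    FWR,
    IGNORED,
    MotifSpec,
    RegionMask,
)
from .phylo_likelihood import LineageData, Repertoire
from .substitution_models import RATE_FLOOR, ModelParams
from .trees import GERMLINE_LABEL, LineageTree, TreeNode

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# lookup tables over the 64-codon space (index = 16*b0 + 4*b1 + b2)
# ---------------------------------------------------------------------------

_AA64 = np.full(64, -1, dtype=np.int8)
_SENSE64 = np.zeros(64, dtype=bool)
for _i, _c in enumerate(itertools.product(NUCLEOTIDES, repeat=3)):
    _codon = "".join(_c)
    if _codon in CODON_SPACE.index_of:
        _SENSE64[_i] = True
        _AA64[_i] = ord(CODON_SPACE.amino_acid_of[_codon])

_TS = np.zeros((4, 4), dtype=bool)  # A C G T; transitions A<->G, C<->T
_TS[0, 2] = _TS[2, 0] = _TS[1, 3] = _TS[3, 1] = True

_ALT = np.array([[b for b in range(4) if b != a] for a in range(4)])  # (4,3)

_SENSE61_TO_64 = np.array([16 * CODON_SPACE.codon_nt[i, 0]
                           + 4 * CODON_SPACE.codon_nt[i, 1]
                           + CODON_SPACE.codon_nt[i, 2] for i in range(61)])
_C64_TO_61 = np.full(64, -1)
_C64_TO_61[_SENSE61_TO_64] = np.arange(61)

#: Per-motif boolean match tables: _MOTIF_ALLOWED[name][k] is a length-4
#: bool array over nucleotides for pattern position k.
_MOTIF_ALLOWED = {
    name: np.array([[b in m.allowed(k) for b in NUCLEOTIDES]
                    for k in range(len(m.pattern))])
    for name, m in MOTIFS.items()
}


def _encode(seq: str) -> np.ndarray:
    return np.array([NUCLEOTIDES.index(b) for b in seq.upper()], dtype=np.int64)


def _decode(arr: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[int(b)] for b in arr)


def _motif_target_mask(s: np.ndarray, motif_name: str) -> np.ndarray:
    """Boolean array: position i is the target base of an occurrence of the
    motif in sequence s (overlaps allowed)."""
    allowed = _MOTIF_ALLOWED[motif_name]
    m = len(allowed)
    n = len(s)
    out = np.zeros(n, dtype=bool)
    if n < m:
        return out
    match = np.ones(n - m + 1, dtype=bool)
    for k in range(m):
        match &= allowed[k][s[k:n - m + 1 + k]]
    offset = MOTIFS[motif_name].target_offset
    out[np.flatnonzero(match) + offset] = True
    return out


def _hlp_rate_table(s: np.ndarray, omega_site: np.ndarray, params: ModelParams,
                    with_h: bool = True) -> np.ndarray:
    """(3L, 3) relative substitution rates of each position to its three
    alternative bases under the full-context HLP19 process."""
    L3 = len(s)
    c64 = 16 * s[0::3] + 4 * s[1::3] + s[2::3]
    pos_mult = np.tile([16, 4, 1], L3 // 3)
    cod = np.repeat(c64, 3)
    alt = _ALT[s]                                  # (3L, 3) alternative bases
    newcod = cod[:, None] + (alt - s[:, None]) * pos_mult[:, None]
    sense = _SENSE64[newcod]
    nonsyn = _AA64[cod][:, None] != _AA64[newcod]
    ts = _TS[s[:, None], alt]
    omega_pos = np.repeat(omega_site, 3)           # per-codon omega -> per-base
    rates = np.where(ts, params.kappa, 1.0) * np.where(nonsyn, omega_pos[:, None], 1.0)
    if with_h:
        hmult = np.ones(L3)
        for m in MOTIF_NAMES:
            hm = params.h.get(m, 0.0)
            if hm:
                hmult += hm * _motif_target_mask(s, m)
        np.maximum(hmult, RATE_FLOOR, out=hmult)
        rates = rates * hmult[:, None]
    return np.where(sense, rates, 0.0)


def _omega_per_codon(mask: RegionMask, params: ModelParams) -> np.ndarray:
    return np.array([params.omega_cdr if l == CDR else params.omega_fwr
                     for l in mask.labels])


def _gillespie(seq: np.ndarray, blen: float, rate_fn, z: float,
               rng: np.random.Generator) -> np.ndarray:
    """Evolve one branch: exponential waiting times, event chosen in
    proportion to the current rate table; rates refreshed after every
    substitution.  ``z`` converts relative rates to branch-length units."""
    s = seq.copy()
    t = 0.0
    while True:
        rates = rate_fn(s)
        total = rates.sum()
        if total <= 0:
            return s
        t += rng.exponential(z / total)
        if t > blen:
            return s
        flat = rates.ravel()
        k = rng.choice(flat.size, p=flat / total)
        pos, which = divmod(k, 3)
        s[pos] = _ALT[s[pos], which]


def evolve_hlp19_full_context(germline: str, tree: LineageTree, params: ModelParams,
                              seed: int, mask: RegionMask | None = None) -> dict[str, str]:
    """Simulate tip sequences under the fully context-dependent HLP19
    process along ``tree`` (rooted at the germline).

    Returns tip label -> nucleotide sequence.  Branch lengths mean
    expected substitutions per codon under the h=0 normalization at the
    germline composition; with hot spots present the realized per-codon
    substitution count is correspondingly higher.
    """
    rng = np.random.default_rng(seed)
    mask = mask or RegionMask.uniform(len(germline) // 3)
    omega_site = _omega_per_codon(mask, params)
    g = _encode(germline)
    L = len(g) // 3

    base = _hlp_rate_table(g, omega_site, params, with_h=False)
    z = base.sum() / L  # relative rate per codon at the germline, h=0

    def rate_fn(s: np.ndarray) -> np.ndarray:
        return _hlp_rate_table(s, omega_site, params, with_h=True)

    out: dict[str, str] = {}

    def _down(node: TreeNode, s: np.ndarray) -> None:
        for c in node.children:
            cs = _gillespie(s, c.length, rate_fn, z, rng)
            if c.is_tip:
                out[c.label] = _decode(cs)
            else:
                _down(c, cs)

    _down(tree.root, g)
    return out


# ---------------------------------------------------------------------------
# S5F-style 5-mer mutability tables
# ---------------------------------------------------------------------------

@dataclass
class MutabilityTable:
    """A 5-mer mutability and substitution-profile table.

    ``mutability`` maps each fully determined 5-mer to a nonnegative score
    (relative rate of the center base); ``profile`` maps it to a
    distribution over the three alternative center bases.  5-mers not in
    the table (e.g. at sequence edges, looked up with N placeholders) fall
    back to the average of all matching entries.
    """

    mutability: dict[str, float]
    profile: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self._fallback_cache: dict[str, float] = {}
        for fm, prof in self.profile.items():
            tot = sum(prof.values())
            if tot > 0 and abs(tot - 1.0) > 1e-6:
                raise ValueError(f"substitution profile for {fm} does not sum to 1")

    def lookup(self, fivemer: str) -> float:
        v = self.mutability.get(fivemer)
        if v is not None:
            return v
        if fivemer in self._fallback_cache:
            return self._fallback_cache[fivemer]
        sets = [IUPAC.get(b, IUPAC["N"]) for b in fivemer]
        matches = [m for fm, m in self.mutability.items()
                   if all(fm[k] in sets[k] for k in range(5))]
        v = float(np.mean(matches)) if matches else 1.0
        logger.debug("mutability fallback for %s -> %.4g over %d entries",
                     fivemer, v, len(matches))
        self._fallback_cache[fivemer] = v
        return v

    def profile_of(self, fivemer: str) -> dict[str, float]:
        p = self.profile.get(fivemer)
        if p is not None:
            return p
        center = fivemer[2]
        alts = [b for b in NUCLEOTIDES if b != center]
        return {b: 1.0 / 3.0 for b in alts}

    # -- constructors ----------------------------------------------------
    @classmethod
    def uniform(cls) -> "MutabilityTable":
        """All 5-mers equally mutable; context-free substitution."""
        mut, prof = {}, {}
        for fm in map("".join, itertools.product(NUCLEOTIDES, repeat=5)):
            mut[fm] = 1.0
            alts = [b for b in NUCLEOTIDES if b != fm[2]]
            prof[fm] = {b: 1.0 / 3.0 for b in alts}
        return cls(mut, prof)

    @classmethod
    def synthetic(cls, kappa: float = 2.0,
                  h: dict[str, float] | None = None) -> "MutabilityTable":
        """A synthetic stand-in for empirical SHM targeting tables (the
        published tables cannot be redistributed here): the mutability of
        a 5-mer is the product of (1 + h_m) over motifs whose target base
        is the center, and substitution profiles carry a transition bias.
        Reproduces the qualitative hot/cold ranking
        GYW > WRC ~ WA > TW > SYC ~ GRS."""
        h = h or {"WRC": 4.0, "GYW": 6.0, "WA": 4.0, "TW": 2.0, "SYC": -0.6, "GRS": -0.6}
        mut, prof = {}, {}
        for fm in map("".join, itertools.product(NUCLEOTIDES, repeat=5)):
            score = 1.0
            for name in MOTIF_NAMES:
                if _center_is_target(fm, MOTIFS[name]):
                    score *= 1.0 + h.get(name, 0.0)
            mut[fm] = score
            center = fm[2]
            alts = [b for b in NUCLEOTIDES if b != center]
            w = np.array([kappa if _TS[NUCLEOTIDES.index(center), NUCLEOTIDES.index(b)]
                          else 1.0 for b in alts])
            w = w / w.sum()
            prof[fm] = dict(zip(alts, map(float, w)))
        return cls(mut, prof)

    @classmethod
    def from_tsv(cls, path) -> "MutabilityTable":
        """Read a TSV with columns: fivemer, mutability, then one column
        per substitution target base (A, C, G, T; the center base's own
        column is ignored)."""
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        df.columns = [c.strip().lower() for c in df.columns]
        mut, prof = {}, {}
        for _, row in df.iterrows():
            fm = str(row["fivemer"]).upper()
            mut[fm] = float(row["mutability"])
            p = {b: float(row[b.lower()]) for b in NUCLEOTIDES
                 if b != fm[2] and b.lower() in df.columns}
            tot = sum(p.values())
            if tot > 0:
                p = {b: v / tot for b, v in p.items()}
            prof[fm] = p
        return cls(mut, prof)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = []
        for fm, m in sorted(self.mutability.items()):
            prof = self.profile_of(fm)
            rows.append({"fivemer": fm, "mutability": m,
                         **{b.lower(): prof.get(b, 0.0) for b in NUCLEOTIDES}})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _center_is_target(fivemer: str, motif: MotifSpec) -> bool:
    """True if the center base of the 5-mer is the target of an occurrence
    of the motif (the motif window fits inside the 5-mer)."""
    start = 2 - motif.target_offset
    if start < 0 or start + len(motif.pattern) > 5:
        return False
    return all(fivemer[start + k] in motif.allowed(k)
               for k in range(len(motif.pattern)))


def motif_mean_mutability(table: MutabilityTable, motif: MotifSpec) -> float:
    """Mean mutability over all 5-mers whose center base is the motif's
    target within a matching occurrence, with uniform 5-mer weighting."""
    vals = [table.lookup(fm) for fm in map("".join, itertools.product(NUCLEOTIDES, repeat=5))
            if _center_is_target(fm, motif)]
    if not vals:
        raise ValueError(f"no pentamers match motif {motif.name}")
    return float(np.mean(vals))


def evolve_s5f(germline: str, tree: LineageTree, table: MutabilityTable,
               seed: int, mask: RegionMask | None = None) -> dict[str, str]:
    """Simulate tip sequences with per-base rates proportional to 5-mer
    mutability and substitution identities drawn from the table's
    profiles; changes creating stop codons are disallowed."""
    rng = np.random.default_rng(seed)
    g = _encode(germline)
    L = len(g) // 3

    def rate_fn(s: np.ndarray) -> np.ndarray:
        seq = _decode(s)
        padded = "NN" + seq + "NN"
        rates = np.zeros((len(s), 3))
        c64 = 16 * s[0::3] + 4 * s[1::3] + s[2::3]
        pos_mult = np.tile([16, 4, 1], L)
        cod = np.repeat(c64, 3)
        for i in range(len(s)):
            fm = padded[i:i + 5]
            mut = table.lookup(fm)
            prof = table.profile_of(fm)
            for k, b in enumerate(_ALT[s[i]]):
                newc = cod[i] + (b - s[i]) * pos_mult[i]
                if _SENSE64[newc]:
                    rates[i, k] = mut * prof.get(NUCLEOTIDES[int(b)], 0.0)
        return rates

    z = rate_fn(g).sum() / L

    out: dict[str, str] = {}

    def _down(node: TreeNode, s: np.ndarray) -> None:
        for c in node.children:
            cs = _gillespie(s, c.length, rate_fn, z, rng)
            if c.is_tip:
                out[c.label] = _decode(cs)
            else:
                _down(c, cs)

    _down(tree.root, g)
    return out


# ---------------------------------------------------------------------------
# repertoire fixtures
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Configuration of a synthetic-repertoire draw.

    Defaults reflect the study conditions used for validation: clone sizes
    power-law distributed with ~92% singletons, 100-codon V regions with a
    quarter of scored sites in two CDR blocks and a trailing IGNORED CDR3
    stub, coalescent lineage trees rescaled to 0.3 expected substitutions
    per codon, and the reference parameter set (kappa=2, omega_FWR=0.5,
    omega_CDR=0.7, h = 4/6/4/2/-0.6/-0.6 for WRC/GYW/WA/TW/SYC/GRS).
    """

    n_lineages: int = 50
    clone_size_law: tuple = ("power_law", 3.95)
    max_clone_size: int = 100
    n_codons: int = 100
    cdr_fraction: float = 0.25
    tree_law: str = "random_coalescent"
    supplied_trees: list | None = None
    branch_scale: float = 0.3
    params: ModelParams = field(default_factory=lambda: default_sim_params())
    generator: str = "HLP19_full_context"
    mutability: MutabilityTable | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_lineages < 1 or self.n_codons < 1 or self.max_clone_size < 1:
            raise ValueError("counts must be positive")
        if not (0 < self.cdr_fraction < 1):
            raise ValueError("cdr_fraction must be in (0, 1)")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.generator not in ("HLP19_full_context", "S5F_table"):
            raise ValueError(f"unknown generator {self.generator!r}")
        law = self.clone_size_law[0]
        if law not in ("power_law", "fixed"):
            raise ValueError(f"unknown clone size law {law!r}")


def default_sim_params() -> ModelParams:
    """The reference generating parameter set used throughout validation."""
    return ModelParams(
        kappa=2.0, omega_fwr=0.5, omega_cdr=0.7,
        h={"WRC": 4.0, "GYW": 6.0, "WA": 4.0, "TW": 2.0, "SYC": -0.6, "GRS": -0.6},
    )


def draw_clone_sizes(n: int, law: tuple, rng: np.random.Generator,
                     max_size: int = 100) -> np.ndarray:
    """Clone sizes (unique sequences per clone) under a truncated power law
    P(k) ~ k^-exponent, k = 1..max_size, or a fixed size."""
    kind = law[0]
    if kind == "fixed":
        return np.full(n, int(law[1]))
    exponent = float(law[1])
    k = np.arange(1, max_size + 1)
    p = k.astype(float) ** -exponent
    p /= p.sum()
    return rng.choice(k, size=n, p=p)


def make_vregion_mask(n_codons: int, cdr_fraction: float = 0.25,
                      cdr3_fraction: float = 0.05) -> RegionMask:
    """FWR background with two contiguous CDR blocks (around 30% and 60%
    of the region) and a trailing IGNORED block standing in for the
    removed CDR3."""
    labels = [FWR] * n_codons
    n_cdr = max(int(round(cdr_fraction * n_codons)), 2)
    block1 = n_cdr // 2
    block2 = n_cdr - block1
    s1 = int(0.30 * n_codons)
    s2 = int(0.60 * n_codons)
    for i in range(s1, min(s1 + block1, n_codons)):
        labels[i] = CDR
    for i in range(s2, min(s2 + block2, n_codons)):
        labels[i] = CDR
    n_ign = int(round(cdr3_fraction * n_codons))
    for i in range(n_codons - n_ign, n_codons):
        labels[i] = IGNORED
    return RegionMask(tuple(labels))


def random_coalescent_tree(n_tips: int, rng: np.random.Generator,
                           labels: list[str], total_length: float) -> LineageTree:
    """Kingman coalescent over exchangeable tips with the germline grafted
    above the MRCA; all branch lengths rescaled so the tree length (sum of
    branches, germline trunk included) equals ``total_length``."""
    root = TreeNode(GERMLINE_LABEL)
    if n_tips == 1:
        tip = TreeNode(labels[0], total_length)
        root.add_child(tip)
        return LineageTree(root)
    nodes = [TreeNode(l) for l in labels]
    height = {id(n): 0.0 for n in nodes}
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = TreeNode(None)
        parent.add_child(a)
        parent.add_child(b)
        a.length = t - height[id(a)]
        b.length = t - height[id(b)]
        height[id(parent)] = t
        nodes = [n for n in nodes if n is not a and n is not b] + [parent]
    mrca = nodes[0]
    mrca.length = rng.exponential(1.0)  # germline trunk
    root.add_child(mrca)
    tree = LineageTree(root)
    factor = total_length / tree.tree_length()
    tree.set_branch_lengths(tree.branch_lengths() * factor)
    return tree


def generate_repertoire_fixture(config: SimConfig, out_dir: str | None = None) -> Repertoire:
    """Draw a synthetic repertoire (deterministic given ``config.seed``)
    and optionally write FASTA/AIRR/Newick/manifest files to ``out_dir``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mask = make_vregion_mask(config.n_codons, config.cdr_fraction)
    sizes = draw_clone_sizes(config.n_lineages, config.clone_size_law, rng,
                             config.max_clone_size)
    table = config.mutability
    if config.generator == "S5F_table" and table is None:
        table = MutabilityTable.synthetic()

    lineages: list[LineageData] = []
    for li, size in enumerate(sizes):
        name = f"clone{li}"
        for _ in range(20):  # stop-free by construction; guard anyway
            germ_idx = rng.integers(0, 61, size=config.n_codons)
            germline = "".join(CODON_SPACE.codons[i] for i in germ_idx)
            if all(germline[3 * i: 3 * i + 3] not in ("TAA", "TAG", "TGA")
                   for i in range(config.n_codons)):
                break
        labels = [f"{name}_s{i}" for i in range(size)]
        if config.tree_law == "supplied":
            tree = config.supplied_trees[li]
        else:
            tree = random_coalescent_tree(int(size), rng, labels, config.branch_scale)
        evolve_seed = int(rng.integers(0, 2**31 - 1))
        if config.generator == "HLP19_full_context":
            tips = evolve_hlp19_full_context(germline, tree, config.params,
                                             evolve_seed, mask)
        else:
            tips = evolve_s5f(germline, tree, table, evolve_seed, mask)
        lineages.append(LineageData(name=name, sequences=tips, germline=germline,
                                    mask=mask, tree=tree))

    rep = Repertoire(lineages=lineages, params=config.params, model_tag="hlp19")
    if out_dir is not None:
        _write_fixture(rep, config, out_dir)
    return rep


def _write_fixture(rep: Repertoire, config: SimConfig, out_dir: str) -> None:
    from . import io as _io

    os.makedirs(out_dir, exist_ok=True)
    _io.write_airr(rep, os.path.join(out_dir, "repertoire.airr.tsv"))
    _io.write_mask_tsv(rep.lineages[0].mask, os.path.join(out_dir, "mask.tsv"))
    from .trees import write_trees_tsv

    write_trees_tsv({lin.name: lin.tree for lin in rep.lineages},
                    os.path.join(out_dir, "trees.tsv"))
    for lin in rep.lineages:
        with open(os.path.join(out_dir, f"{lin.name}.fasta"), "w") as fh:
            fh.write(f">{GERMLINE_LABEL}\n{lin.germline}\n")
            for sid, seq in lin.sequences.items():
                fh.write(f">{sid}\n{seq}\n")
    p = config.params
    manifest = {
        "seed": config.seed,
        "n_lineages": config.n_lineages,
        "n_codons": config.n_codons,
        "generator": config.generator,
        "branch_scale": config.branch_scale,
        "truth": {
            "kappa": p.kappa, "omega_fwr": p.omega_fwr, "omega_cdr": p.omega_cdr,
            **{f"h_{m.lower()}": p.h[m] for m in MOTIF_NAMES},
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def subsample_repertoire(rep: Repertoire, depth: int, seed: int) -> Repertoire:
    """Subsample sequences in nonsingleton clones down to ``depth`` (uniform,
    without replacement); clones left with fewer than 2 unique sequences
    are dropped; singleton clones are untouched.  Subsampled lineages lose
    their trees (topologies must be re-estimated)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    pool = [(i, sid) for i, lin in enumerate(rep.lineages)
            if lin.n_unique_sequences() >= 2 for sid in lin.sequences]
    if depth >= len(pool):
        logger.warning("subsample depth %d >= available %d; returning repertoire unchanged",
                       depth, len(pool))
        return rep
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=depth, replace=False)
    keep: dict[int, set] = {}
    for k in chosen:
        i, sid = pool[int(k)]
        keep.setdefault(i, set()).add(sid)
    lineages: list[LineageData] = []
    for i, lin in enumerate(rep.lineages):
        if lin.n_unique_sequences() < 2:
            lineages.append(lin)
            continue
        sel = keep.get(i, set())
        seqs = {sid: s for sid, s in lin.sequences.items() if sid in sel}
        if len(set(seqs.values())) < 2:
            continue
        lineages.append(replace(lin, sequences=seqs, tree=None,
                                multiplicity={}))
    return Repertoire(lineages=lineages, params=rep.params, model_tag=rep.model_tag)
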