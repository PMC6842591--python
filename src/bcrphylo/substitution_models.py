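"""Codon rate matrices for B-cell receptor evolution: GY94, HLP17, HLP19.

All three models are 61x61 instantaneous-rate (Q) matrices over the sense
codons, allowing only single-nucleotide changes per instant.  GY94 is the
classical reversible codon model with target-codon frequencies; the HLP
models add somatic-hypermutation context through a vector of per-motif rate
offsets h, so that a substitution whose site sits in (say) a GYW hot spot
occurs at (1 + h_GYW) times the base rate.  Because motifs can straddle
codon boundaries while the likelihood machinery factorizes over codon
sites, the flanking context is marginalized with a mean-field
approximation: in-codon motif positions are read off the (pre-mutation)
source codon, out-of-codon positions are replaced by position-specific
nucleotide marginals of the codon frequency vector pi.

HLP19 drops GY94's target-frequency factor and instead normalizes against
the predicted codon frequencies at the midpoint of the phylogeny,
accounting for the nonstationarity of affinity maturation (sequences start
at the germline, far from mutational equilibrium).  HLP17 keeps the pi_b
factor on top of the motif terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .codon_space import (
    CODON_SPACE,
    MOTIF_NAMES,
    MOTIFS,
    NT_INDEX,
    CodonSpace,
    MotifSpec,
    is_transition_pair,
)

logger = logging.getLogger(__name__)

N_CODONS = CODON_SPACE.n

#: Rate floor applied when cold-spot offsets drive a motif multiplier <= 0.
RATE_FLOOR = 1e-9


def _single_nt_changes() -> dict[str, np.ndarray]:
    """Precompute the allowed single-nucleotide codon changes.

    Returns parallel arrays: source index, target index, changed position,
    transition flag, synonymous flag.
    """
    a_idx, b_idx, pos, is_ts, is_syn = [], [], [], [], []
    for i, ca in enumerate(CODON_SPACE.codons):
        for j, cb in enumerate(CODON_SPACE.codons):
            if i == j:
                continue
            diff = [p for p in range(3) if ca[p] != cb[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            a_idx.append(i)
            b_idx.append(j)
            pos.append(p)
            is_ts.append(is_transition_pair(ca[p], cb[p]))
            is_syn.append(CODON_SPACE.amino_acid_of[ca] == CODON_SPACE.amino_acid_of[cb])
    return {
        "a": np.array(a_idx), "b": np.array(b_idx), "pos": np.array(pos),
        "is_ts": np.array(is_ts), "is_syn": np.array(is_syn),
    }


_CHANGES = _single_nt_changes()


@dataclass
class ModelParams:
    """Free parameters of the HLP-family models.

    kappa : transition/transversion rate ratio (> 0)
    omega_fwr, omega_cdr : dN/dS for framework and CDR codon sites (> 0)
    h : motif name -> additive rate offset in (-1, inf); the substitution
        rate of a motif's target base is multiplied by (1 + h)
    pi : 61-vector of codon frequencies (sums to 1); for HLP19 this is the
        predicted midpoint frequency vector, for GY94/HLP17 the empirical
        repertoire frequencies
    """

    kappa: float = 2.0
    omega_fwr: float = 0.4
    omega_cdr: float = 0.4
    h: dict[str, float] = field(default_factory=lambda: {m: 0.0 for m in MOTIF_NAMES})
    pi: np.ndarray = field(default_factory=lambda: np.full(N_CODONS, 1.0 / N_CODONS))

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        for m in MOTIF_NAMES:
            self.h.setdefault(m, 0.0)

    def validate(self) -> None:
        if not (self.kappa > 0 and self.omega_fwr > 0 and self.omega_cdr > 0):
            raise ValueError("kappa and omega values must be positive")
        for m, v in self.h.items():
            if m not in MOTIFS:
                raise ValueError(f"unknown motif {m!r} in h vector")
            if v <= -1:
                raise ValueError(f"h[{m}] = {v} <= -1 would give a non-positive rate multiplier")
        if self.pi.shape != (N_CODONS,):
            raise ValueError("pi must be a 61-vector")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("pi must be nonnegative and sum to 1 (within 1e-12)")

    def omega(self, region: str) -> float:
        return self.omega_cdr if region == "CDR" else self.omega_fwr

    def h_vector(self) -> np.ndarray:
        return np.array([self.h[m] for m in MOTIF_NAMES])

    def with_pi(self, pi: np.ndarray) -> "ModelParams":
        return replace(self, h=dict(self.h), pi=np.asarray(pi, dtype=float))


@dataclass
class RateMatrix:
    """A normalized instantaneous-rate matrix.

    ``q`` has rows summing to zero; ``scale`` is the divisor applied so
    that the expected number of substitutions per codon per unit time,
    -sum_a pibar_a q_aa, equals 1 under the normalizing frequencies.
    """

    q: np.ndarray
    scale: float
    model_tag: str
    region: str

    def to_tsv(self, path) -> None:
        """Serialize to a tab-separated matrix with codon labels."""
        import pandas as pd

        pd.DataFrame(self.q, index=CODON_SPACE.codons, columns=CODON_SPACE.codons).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class ContextExpectation:
    """Mean-field motif context probabilities.

    ``e[a, p, m]`` is the probability that nucleotide position p of source
    codon a is the target base of an occurrence of motif m, with
    cross-boundary positions marginalized over pi.
    """

    e: np.ndarray  # (61, 3, n_motifs)
    motif_names: tuple[str, ...]


def positional_nt_marginals(pi: np.ndarray) -> np.ndarray:
    """(3, 4) marginal nucleotide frequencies by codon position under pi."""
    marg = np.zeros((3, 4))
    for i in range(N_CODONS):
        for p in range(3):
            marg[p, CODON_SPACE.codon_nt[i, p]] += pi[i]
    return marg


def mean_field_context(
    codon_space: CodonSpace = CODON_SPACE,
    motifs: dict[str, MotifSpec] | None = None,
    pi: np.ndarray | None = None,
) -> ContextExpectation:
    """Probability that each codon position is a motif target, marginalizing
    flanking positions over pi's positional nucleotide marginals.

    Within-codon motif positions are evaluated on the source codon's own
    bases (SHM acts on the pre-mutation state), so fully within-codon
    placements give probabilities of exactly 0 or 1.  A position k bases
    into the left flank uses the marginal of codon position 3-k+1 of the
    preceding codon; symmetrically on the right.
    """
    motifs = motifs or MOTIFS
    pi = np.full(N_CODONS, 1.0 / N_CODONS) if pi is None else np.asarray(pi, float)
    marg = positional_nt_marginals(pi)
    names = tuple(motifs)
    e = np.ones((N_CODONS, 3, len(names)))
    for mi, name in enumerate(names):
        motif = motifs[name]
        for a in range(N_CODONS):
            codon = codon_space.codons[a]
            for p in range(3):
                prob = 1.0
                for k in range(len(motif.pattern)):
                    abs_pos = p - motif.target_offset + k
                    allowed = motif.allowed(k)
                    if 0 <= abs_pos <= 2:
                        prob *= 1.0 if codon[abs_pos] in allowed else 0.0
                    else:
                        # out-of-codon: abs_pos in {-2,-1} maps to positions
                        # {1,2} of the previous codon; {3,4} to {0,1} of the
                        # next codon
                        flank_pos = abs_pos + 3 if abs_pos < 0 else abs_pos - 3
                        prob *= sum(marg[flank_pos, NT_INDEX[b]] for b in allowed)
                    if prob == 0.0:
                        break
                e[a, p, mi] = prob
    return ContextExpectation(e=e, motif_names=names)


def _motif_multiplier(params: ModelParams, context: ContextExpectation) -> np.ndarray:
    """(n_changes,) multiplier 1 + sum_m h_m e(a, p, m), floored at RATE_FLOOR."""
    hvec = np.array([params.h.get(m, 0.0) for m in context.motif_names])
    e_ap = context.e[_CHANGES["a"], _CHANGES["pos"], :]  # (n_changes, n_motifs)
    mult = 1.0 + e_ap @ hvec
    return np.maximum(mult, RATE_FLOOR)


def _assemble(rates: np.ndarray, pibar: np.ndarray, model_tag: str, region: str) -> RateMatrix:
    q = np.zeros((N_CODONS, N_CODONS))
    q[_CHANGES["a"], _CHANGES["b"]] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = float(-(pibar * np.diag(q)).sum())
    if scale <= 0:
        raise ValueError("degenerate rate matrix: zero mean rate")
    return RateMatrix(q=q / scale, scale=scale, model_tag=model_tag, region=region)


def build_q_hlp19(params: ModelParams, region: str, context: ContextExpectation) -> RateMatrix:
    """HLP19 Q matrix: rate of a -> b (single-base change) is
    kappa^[transition] * omega_region^[nonsynonymous] * (1 + sum_m h_m e(a,p,m)),
    normalized so the mean substitution rate per codon is 1 under params.pi
    (the midpoint frequencies)."""
    params.validate()
    omega = params.omega(region)
    rates = (
        np.where(_CHANGES["is_ts"], params.kappa, 1.0)
        * np.where(_CHANGES["is_syn"], 1.0, omega)
        * _motif_multiplier(params, context)
    )
    return _assemble(rates, params.pi, "HLP19", region)


def build_q_hlp17(params: ModelParams, region: str, context: ContextExpectation) -> RateMatrix:
    """HLP17 Q matrix: as HLP19 but each entry additionally multiplied by
    the frequency of the target codon pi_b (GY94-style)."""
    params.validate()
    omega = params.omega(region)
    rates = (
        params.pi[_CHANGES["b"]]
        * np.where(_CHANGES["is_ts"], params.kappa, 1.0)
        * np.where(_CHANGES["is_syn"], 1.0, omega)
        * _motif_multiplier(params, context)
    )
    return _assemble(rates, params.pi, "HLP17", region)


def build_q_gy94(params: ModelParams, region: str) -> RateMatrix:
    """GY94 Q matrix: q_ab = pi_b * kappa^[transition] * omega^[nonsyn]."""
    params.validate()
    omega = params.omega(region)
    rates = (
        params.pi[_CHANGES["b"]]
        * np.where(_CHANGES["is_ts"], params.kappa, 1.0)
        * np.where(_CHANGES["is_syn"], 1.0, omega)
    )
    return _assemble(rates, params.pi, "GY94", region)


def build_q(params: ModelParams, region: str, model_tag: str,
            context: ContextExpectation | None = None) -> RateMatrix:
    tag = model_tag.lower()
    if tag == "gy94":
        return build_q_gy94(params, region)
    if context is None:
        context = mean_field_context(pi=params.pi)
    if tag == "hlp17":
        return build_q_hlp17(params, region, context)
    if tag == "hlp19":
        return build_q_hlp19(params, region, context)
    raise ValueError(f"unknown model tag {model_tag!r}")


def predict_midpoint_frequencies(
    germline_freqs: np.ndarray,
    mean_root_to_tip: float,
    params: ModelParams,
    region: str = "FWR",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Predicted codon frequencies at the midpoint of the phylogeny.

    Fixed point of: build the HLP19 Q under the current frequency guess,
    propagate the germline frequencies for half the mean root-to-tip
    distance, repeat.  The Q is renormalized at each iteration.  Frequency
    propagation uses the FWR matrix (most of a V region is framework).
    """
    if mean_root_to_tip < 0:
        raise ValueError("mean_root_to_tip must be >= 0")
    germline_freqs = np.asarray(germline_freqs, float)
    if mean_root_to_tip == 0:
        return germline_freqs.copy()
    t_mid = mean_root_to_tip / 2.0
    pibar = germline_freqs.copy()
    for _ in range(max_iter):
        ctx = mean_field_context(pi=pibar)
        q = build_q_hlp19(params.with_pi(pibar), region, ctx)
        nxt = germline_freqs @ expm(q.q * t_mid)
        nxt = np.maximum(nxt, 0)
        nxt /= nxt.sum()
        delta = np.abs(nxt - pibar).max()
        pibar = nxt
        if delta < tol:
            return pibar
    logger.warning("midpoint frequency iteration did not converge to %g in %d iterations",
                   tol, max_iter)
    return pibar


def transition_probabilities(q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) for a branch of length t (expected substitutions per
    codon).  Rows sum to 1; entries clipped into [0, 1]."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    mat = q.q if isinstance(q, RateMatrix) else np.asarray(q, float)
    p = expm(mat * t)
    p = np.clip(p, 0.0, 1.0)
    return p


class EigenPropagator:
    """Fast repeated evaluation of P(t) = exp(Qt) via eigendecomposition.

    Q matrices here are nonreversible and generally non-symmetric, so the
    decomposition is complex; the reconstruction is checked and the class
    falls back to scipy's scaling-and-squaring expm if Q is (numerically)
    defective.  Results are cached per branch length.
    """

    def __init__(self, q: np.ndarray):
        self.q = np.asarray(q, float)
        self._cache: dict[float, np.ndarray] = {}
        try:
            w, v = np.linalg.eig(self.q)
            vinv = np.linalg.inv(v)
            err = np.abs((v * w) @ vinv - self.q).max()
            self._ok = err < 1e-9
        except np.linalg.LinAlgError:  # pragma: no cover - extremely rare
            self._ok = False
        if self._ok:
            self._w, self._v, self._vinv = w, v, vinv

    def __call__(self, t: float) -> np.ndarray:
        p = self._cache.get(t)
        if p is None:
            if self._ok:
                p = ((self._v * np.exp(self._w * t)) @ self._vinv).real
            else:
                p = expm(self.q * t)
            np.clip(p, 0.0, 1.0, out=p)
            self._cache[t] = p
        return p
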