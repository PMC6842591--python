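"""Rate-matrix construction: mean-field motif context, GY94/HLP17/HLP19
structure, midpoint frequencies and transition probabilities."""

import numpy as np
import pytest
from scipy.linalg import expm

from bcrphylo.codon_space import CODON_SPACE, IUPAC, MOTIF_NAMES, MOTIFS
from bcrphylo.substitution_models import (
    EigenPropagator,
    ModelParams,
    build_q_gy94,
    build_q_hlp17,
    build_q_hlp19,
    mean_field_context,
    positional_nt_marginals,
    predict_midpoint_frequencies,
    transition_probabilities,
)

UNIFORM = np.full(61, 1 / 61)
IDX = CODON_SPACE.index_of


def random_params(rng):
    return ModelParams(
        kappa=float(rng.uniform(0.2, 10)),
        omega_fwr=float(rng.uniform(0.05, 3)),
        omega_cdr=float(rng.uniform(0.05, 3)),
        h={m: float(rng.uniform(-0.9, 8)) for m in MOTIF_NAMES},
        pi=rng.dirichlet(np.ones(61)),
    )


# ---------------------------------------------------------------------------
# mean-field context
# ---------------------------------------------------------------------------

class TestMeanFieldContext:
    def test_fully_within_codon_contexts_are_deterministic(self):
        ctx = mean_field_context(pi=UNIFORM)
        # TAC position 2 is the C of a WRC occurrence entirely in-codon
        assert ctx.e[IDX["TAC"], 2, ctx.motif_names.index("WRC")] == 1.0
        # GCA position 0: GYW with Y=C, W=A read off the codon itself
        assert ctx.e[IDX["GCA"], 0, ctx.motif_names.index("GYW")] == 1.0
        # AAC position 2 is not SYC (A is not S)
        assert ctx.e[IDX["AAC"], 2, ctx.motif_names.index("SYC")] == 0.0

    def test_left_flank_marginal_matches_enumeration_oracle(self):
        # ACC position 0 is the A of a WA occurrence iff the preceding base
        # (position 3 of the left-flank codon) is A or T; enumerate the 61
        # sense codons under uniform pi
        ctx = mean_field_context(pi=UNIFORM)
        oracle = np.mean([c[2] in "AT" for c in CODON_SPACE.codons])
        got = ctx.e[IDX["ACC"], 0, ctx.motif_names.index("WA")]
        assert got == pytest.approx(oracle)
        assert got == pytest.approx(30 / 61)

    def test_two_base_flank_uses_position_specific_marginals(self):
        # CAA position 0: the C can be a WRC target with W at -2 (position
        # 2 of the left codon) and R at -1 (its position 3); mean field
        # multiplies the two positional marginals
        pi = np.random.default_rng(5).dirichlet(np.ones(61))
        ctx = mean_field_context(pi=pi)
        marg = positional_nt_marginals(pi)
        expect = (marg[1, 0] + marg[1, 3]) * (marg[2, 0] + marg[2, 2])  # W then R
        assert ctx.e[IDX["CAA"], 0, ctx.motif_names.index("WRC")] == pytest.approx(expect)

    def test_entries_are_probabilities(self, rng):
        ctx = mean_field_context(pi=rng.dirichlet(np.ones(61)))
        assert ctx.e.min() >= 0.0 and ctx.e.max() <= 1.0

    def test_degenerate_pi_yields_zero_probability_contexts(self):
        pi = np.zeros(61)
        pi[IDX["CCC"]] = 1.0  # no A/T anywhere in flanks
        ctx = mean_field_context(pi=pi)
        assert ctx.e[IDX["ACC"], 0, ctx.motif_names.index("WA")] == 0.0


# ---------------------------------------------------------------------------
# Q-matrix structure
# ---------------------------------------------------------------------------

def _check_rate_matrix(q, pibar):
    off = q.q - np.diag(np.diag(q.q))
    assert off.min() >= 0
    assert np.abs(q.q.sum(axis=1)).max() < 1e-10
    assert -(pibar * np.diag(q.q)).sum() == pytest.approx(1.0, abs=1e-8)
    # multi-nucleotide changes are forbidden
    for i, a in enumerate(CODON_SPACE.codons[:10]):
        for j, b in enumerate(CODON_SPACE.codons):
            if sum(x != y for x, y in zip(a, b)) > 1:
                assert q.q[i, j] == 0.0


class TestQMatrices:
    def test_invariants_over_random_parameter_draws(self, rng):
        for _ in range(60):
            p = random_params(rng)
            ctx = mean_field_context(pi=p.pi)
            for build in (build_q_gy94,
                          lambda pp, r: build_q_hlp17(pp, r, ctx),
                          lambda pp, r: build_q_hlp19(pp, r, ctx)):
                q = build(p, "CDR")
                _check_rate_matrix(q, p.pi)

    def test_neutral_hlp19_has_equal_permitted_rates(self):
        p = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1, pi=UNIFORM)
        q = build_q_hlp19(p, "FWR", mean_field_context(pi=UNIFORM))
        raw = q.q * q.scale
        vals = raw[raw > 0]
        assert np.allclose(vals, vals[0])

    def test_gy94_transition_ratio_and_stationarity(self):
        p = ModelParams(kappa=2, omega_fwr=1, omega_cdr=1, pi=UNIFORM)
        q = build_q_gy94(p, "FWR")
        # kappa doubles transitions relative to matched transversions
        raw = q.q * q.scale
        assert raw[IDX["AAA"], IDX["AAG"]] == pytest.approx(
            2 * raw[IDX["AAA"], IDX["AAT"]] / 1.0)  # both synonymous Lys->Lys/ Lys->Asn?
        # pi is stationary for GY94
        prand = ModelParams(kappa=3, omega_fwr=0.3, omega_cdr=0.3,
                            pi=np.random.default_rng(2).dirichlet(np.ones(61)))
        qr = build_q_gy94(prand, "FWR")
        assert np.abs(prand.pi @ qr.q).max() < 1e-10

    def test_hlp17_with_zero_h_equals_gy94(self, rng):
        p = random_params(rng)
        p.h = {m: 0.0 for m in MOTIF_NAMES}
        ctx = mean_field_context(pi=p.pi)
        np.testing.assert_allclose(build_q_hlp17(p, "FWR", ctx).q,
                                   build_q_gy94(p, "FWR").q, atol=1e-12)

    def test_hlp19_with_zero_h_is_m0_style(self):
        # no pi_b factor: rates depend only on kappa/omega class
        p = ModelParams(kappa=2.0, omega_fwr=0.5, omega_cdr=0.5, pi=UNIFORM)
        q = build_q_hlp19(p, "FWR", mean_field_context(pi=UNIFORM))
        raw = q.q * q.scale
        assert raw[IDX["AAA"], IDX["AAG"]] == pytest.approx(2.0)       # syn ts
        assert raw[IDX["AAA"], IDX["AAC"]] == pytest.approx(0.5)       # nonsyn tv
        assert raw[IDX["AAA"], IDX["GAA"]] == pytest.approx(1.0)       # nonsyn ts? AAA->GAA Lys->Glu ts
        # transversion synonymous
        assert raw[IDX["CCC"], IDX["CCA"]] == pytest.approx(1.0)

    def test_cold_spot_scales_deterministic_entry_by_1_plus_h(self):
        # TAC -> TAT: position 2 is the C of both a WRC and a SYC context?
        # TAC: T(W) A(R) C -> WRC hot context, deterministic.  Use SYC on
        # GCC: G(S) C(Y) C -> SYC deterministic at position 2.
        base = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1, pi=UNIFORM)
        cold = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1,
                           h={**{m: 0.0 for m in MOTIF_NAMES}, "SYC": -0.6}, pi=UNIFORM)
        ctx = mean_field_context(pi=UNIFORM)
        q0 = build_q_hlp19(base, "FWR", ctx)
        q1 = build_q_hlp19(cold, "FWR", ctx)
        r0 = (q0.q * q0.scale)[IDX["GCC"], IDX["GCA"]]
        r1 = (q1.q * q1.scale)[IDX["GCC"], IDX["GCA"]]
        assert r1 == pytest.approx(0.4 * r0)

    def test_hlp19_matrix_against_elementwise_oracle(self):
        """Every permitted entry cross-checked against an independent
        per-entry computation of the motif context expectation."""
        p = ModelParams(kappa=2.0, omega_fwr=0.5, omega_cdr=0.5,
                        h={**{m: 0.0 for m in MOTIF_NAMES}, "GYW": 6.0}, pi=UNIFORM)
        ctx = mean_field_context(pi=UNIFORM)
        q = build_q_hlp19(p, "FWR", ctx)
        raw = q.q * q.scale
        marg = positional_nt_marginals(UNIFORM)
        motif = MOTIFS["GYW"]

        def oracle_context(a, pos):
            codon = CODON_SPACE.codons[a]
            prob = 1.0
            for k in range(3):
                ap = pos - motif.target_offset + k
                allowed = IUPAC[motif.pattern[k]]
                if 0 <= ap <= 2:
                    prob *= 1.0 if codon[ap] in allowed else 0.0
                else:
                    fp = ap + 3 if ap < 0 else ap - 3
                    prob *= sum(marg[fp, "ACGT".index(b)] for b in allowed)
            return prob

        rng = np.random.default_rng(7)
        for _ in range(400):
            i, j = rng.integers(0, 61, size=2)
            a, b = CODON_SPACE.codons[i], CODON_SPACE.codons[j]
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                assert raw[i, j] == 0 or i == j
                continue
            k = diff[0]
            ts = (a[k] in "AG") == (b[k] in "AG")
            syn = CODON_SPACE.amino_acid_of[a] == CODON_SPACE.amino_acid_of[b]
            expect = (2.0 if ts else 1.0) * (1.0 if syn else 0.5) \
                * (1.0 + 6.0 * oracle_context(i, k))
            assert raw[i, j] == pytest.approx(expect, rel=1e-10)

    def test_reverse_complement_symmetry_on_deterministic_contexts(self):
        """A hot motif and its partner produce mirrored rates for
        substitutions whose context is entirely within the codon (flank
        marginals are skewed by stop exclusion, so only fully in-codon
        contexts mirror exactly)."""
        from bcrphylo.codon_space import revcomp

        h_fwd = {**{m: 0.0 for m in MOTIF_NAMES}, "WRC": 3.0}
        h_rev = {**{m: 0.0 for m in MOTIF_NAMES}, "GYW": 3.0}
        ctx = mean_field_context(pi=UNIFORM)
        qf = build_q_hlp19(ModelParams(1, 1, 1, h=h_fwd, pi=UNIFORM), "FWR", ctx)
        qr = build_q_hlp19(ModelParams(1, 1, 1, h=h_rev, pi=UNIFORM), "FWR", ctx)
        rf, rr = qf.q * qf.scale, qr.q * qr.scale
        # TAC -> TAT (WRC target C, fully in-codon) mirrors GTA -> ATA
        # (GYW target G, fully in-codon); both are the same strand event
        i, j = IDX["TAC"], IDX["TAT"]
        ri, rj = IDX[revcomp("TAC")], IDX[revcomp("TAT")]
        assert rf[i, j] == pytest.approx(rr[ri, rj])

    def test_h_at_or_below_minus_one_rejected(self):
        p = ModelParams(h={**{m: 0.0 for m in MOTIF_NAMES}, "WRC": -1.0})
        with pytest.raises(ValueError, match="h"):
            build_q_hlp19(p, "FWR", mean_field_context(pi=p.pi))


# ---------------------------------------------------------------------------
# midpoint frequencies & transition probabilities
# ---------------------------------------------------------------------------

class TestMidpointFrequencies:
    def test_zero_distance_returns_germline_unchanged(self):
        g = np.random.default_rng(0).dirichlet(np.ones(61))
        out = predict_midpoint_frequencies(g, 0.0, ModelParams())
        np.testing.assert_array_equal(out, g)

    def test_neutral_long_time_limit_is_uniform(self):
        # kappa=1, omega=1, h=0: all permitted rates equal, so Q is
        # symmetric and its stationary distribution (eigenvector oracle)
        # is uniform over the 61 codons
        p = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1)
        g = np.zeros(61)
        g[IDX["AAA"]] = 1.0
        out = predict_midpoint_frequencies(g, 200.0, p)
        ctx = mean_field_context(pi=out)
        q = build_q_hlp19(p.with_pi(out), "FWR", ctx)
        w, v = np.linalg.eig(q.q.T)
        stat = np.abs(v[:, np.argmin(np.abs(w))].real)
        stat /= stat.sum()
        np.testing.assert_allclose(out, stat, atol=1e-6)
        np.testing.assert_allclose(out, np.full(61, 1 / 61), atol=1e-6)

    def test_fixed_point_satisfies_direct_expm_propagation(self):
        g = np.zeros(61)
        g[IDX["AAA"]] = 1.0
        p = ModelParams(kappa=2.0, omega_fwr=1.0, omega_cdr=1.0)
        out = predict_midpoint_frequencies(g, 0.2, p)
        # independent check of the converged fixed point
        ctx = mean_field_context(pi=out)
        q = build_q_hlp19(p.with_pi(out), "FWR", ctx)
        np.testing.assert_allclose(out, g @ expm(q.q * 0.1), atol=1e-7)


class TestTransitionProbabilities:
    def test_identity_at_zero_and_row_sums(self):
        p = ModelParams(pi=np.random.default_rng(3).dirichlet(np.ones(61)))
        q = build_q_gy94(p, "FWR")
        np.testing.assert_allclose(transition_probabilities(q, 0.0), np.eye(61), atol=1e-12)
        pt = transition_probabilities(q, 0.7)
        assert np.abs(pt.sum(axis=1) - 1).max() < 1e-10
        assert pt.min() >= 0 and pt.max() <= 1

    def test_chapman_kolmogorov(self):
        p = ModelParams()
        ctx = mean_field_context(pi=p.pi)
        q = build_q_hlp19(p, "CDR", ctx)
        p1 = transition_probabilities(q, 0.3)
        p2 = transition_probabilities(q, 0.5)
        p12 = transition_probabilities(q, 0.8)
        np.testing.assert_allclose(p1 @ p2, p12, atol=1e-8)

    def test_gy94_long_time_rows_approach_pi(self):
        pi = np.random.default_rng(9).dirichlet(np.ones(61) * 5)
        q = build_q_gy94(ModelParams(pi=pi), "FWR")
        pt = transition_probabilities(q, 500.0)
        np.testing.assert_allclose(pt, np.tile(pi, (61, 1)), atol=1e-6)

    def test_negative_branch_rejected(self):
        q = build_q_gy94(ModelParams(), "FWR")
        with pytest.raises(ValueError):
            transition_probabilities(q, -0.1)

    def test_eigen_propagator_matches_expm(self):
        p = ModelParams(kappa=3.0, omega_fwr=0.2, omega_cdr=0.9,
                        h={m: v for m, v in zip(MOTIF_NAMES, [4, 6, 4, 2, -0.6, -0.6])})
        ctx = mean_field_context(pi=p.pi)
        q = build_q_hlp19(p, "CDR", ctx)
        prop = EigenPropagator(q.q)
        for t in (0.0, 0.01, 0.4, 2.0):
            np.testing.assert_allclose(prop(t), expm(q.q * t), atol=1e-9)
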