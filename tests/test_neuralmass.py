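"""Generative model: network graph, linearization, spectra, simulation."""

import numpy as np
import pytest

from gripdcm.neuralmass import (DCMModel, build_grasping_network, default_model,
                                drift, linearize, parameter_names, predict_csd,
                                predict_csd_many, simulate_timeseries)
from gripdcm.spectral import SpectralModes, estimate_csd


class TestGraph:
    def test_grasping_network_has_14_extrinsic_edges(self):
        g = build_grasping_network()
        assert g.n_extrinsic == 14
        assert len(g.forward) == 6 and len(g.backward) == 6 and len(g.lateral) == 2

    def test_no_self_edges_and_disjoint_types(self):
        g = build_grasping_network()
        for _, s, d in g.edges():
            assert s != d
        assert not (set(g.forward) & set(g.backward))
        assert not (set(g.forward) & set(g.lateral))

    def test_removing_ipl_edges_leaves_ten(self):
        g = build_grasping_network()
        rest = [e for e in g.edges() if "IPL" not in e[1:]]
        assert len(rest) == 10

    def test_parameter_vector_layout(self):
        g = build_grasping_network()
        names = parameter_names(g)
        assert sum(n.startswith("A:") for n in names) == 14
        assert len(names) == 14 + 5 + 5 + 4


class TestLinearization:
    def test_jacobian_matches_finite_differences_of_drift(self, model):
        rng = np.random.default_rng(0)
        m = model.with_couplings(rng.normal(0, 0.3, 14))
        lin = linearize(m)
        n = lin.J.shape[0]
        h = 1e-6
        J_fd = np.empty((n, n))
        for j in range(n):
            xp, xm = np.zeros(n), np.zeros(n)
            xp[j] += h
            xm[j] -= h
            J_fd[:, j] = (drift(m, xp) - drift(m, xm)) / (2 * h)
        assert np.allclose(lin.J, J_fd, rtol=1e-5, atol=1e-4)

    def test_innovation_map_matches_drift_derivative(self, model):
        lin = linearize(model)
        h = 1e-6
        u = np.zeros(5)
        u[2] = h
        col = (drift(model, np.zeros(40), u) - drift(model, np.zeros(40))) / h
        assert np.allclose(lin.B[:, 2], col, atol=1e-6)

    def test_zeroed_couplings_decouple_sources(self, model):
        m = model.with_couplings(np.full(14, -700.0))    # exp underflows to 0
        J = linearize(m).J
        for i in range(5):
            for j in range(5):
                if i != j:
                    blk = J[i * 8:(i + 1) * 8, j * 8:(j + 1) * 8]
                    # exp(-700) underflows to subnormal ~1e-304 couplings
                    assert np.all(np.abs(blk) < 1e-250)

    def test_default_model_is_stable(self, model):
        lin = linearize(model)
        assert lin.stable
        assert lin.eigenvalues.real.max() < 0

    def test_backward_edge_removal_leaves_stellate_input_unchanged(self, model):
        theta = np.zeros(14)
        theta[6] = -700.0      # zero the first backward edge
        J0 = linearize(model).J
        J1 = linearize(model.with_couplings(theta)).J
        stellate_rows = np.concatenate([[8 * i, 8 * i + 1] for i in range(5)])
        assert np.allclose(J0[stellate_rows], J1[stellate_rows])
        assert not np.allclose(J0, J1)


class TestPredictedSpectra:
    def test_flat_innovations_spectrum_at_default_exponent(self, model, freqs):
        gu = model.nuisance.innovations_power(freqs)
        assert np.all(np.abs(gu[0] / gu[-1] - 1.0) < 1e-10)

    def test_hermitian_psd_output(self, model, freqs):
        cs = predict_csd(model, freqs)
        assert cs.hermitian_error() == 0.0
        diag = np.diagonal(cs.G, axis1=1, axis2=2)
        assert np.all(diag.imag == 0.0)
        assert np.all(diag.real >= 0.0)
        for G in cs.G:
            assert np.linalg.eigvalsh(G).min() >= -1e-12 * np.abs(G).max()

    def test_every_coupling_is_identifiable_in_spectra(self, model, freqs):
        base = predict_csd(model, freqs).G
        for e in range(14):
            th = np.zeros(14)
            th[e] = 0.3
            pert = predict_csd(model.with_couplings(th), freqs).G
            assert np.linalg.norm(pert - base) > 1e-8 * np.linalg.norm(base)

    def test_batched_prediction_matches_single(self, model, freqs):
        rng = np.random.default_rng(1)
        models = [model.with_couplings(rng.normal(0, 0.2, 14)) for _ in range(3)]
        batch = predict_csd_many(models, freqs)
        for i, m in enumerate(models):
            assert np.allclose(batch[i], predict_csd(m, freqs).G, atol=1e-15)

    def test_json_roundtrip(self, model, freqs):
        m2 = DCMModel.from_json(model.to_json())
        assert np.allclose(predict_csd(m2, freqs).G, predict_csd(model, freqs).G)


class TestSimulation:
    def test_same_seed_reproducible(self, model):
        a = simulate_timeseries(model, duration=2.0, rate=128.0, seed=7)
        b = simulate_timeseries(model, duration=2.0, rate=128.0, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_zero_innovations_and_noise_give_zero_output(self, model):
        ts = simulate_timeseries(model, duration=2.0, rate=128.0, seed=0,
                                 innovation_scale=0.0, noise_scale=0.0)
        assert np.allclose(ts.data, 0.0)

    def test_empirical_spectrum_converges_to_prediction(self, model, freqs):
        ts = simulate_timeseries(model, duration=600.0, rate=256.0, seed=3)
        sm = SpectralModes(np.eye(4), ts.data, rate=ts.rate)
        emp = estimate_csd(sm, 4, 48, method="welch")
        ana = predict_csd(model, freqs)
        emp_d = np.diagonal(emp.G, axis1=1, axis2=2).real
        ana_d = np.diagonal(ana.G, axis1=1, axis2=2).real
        # band-integrated per-mode power within 10 %
        assert np.allclose(emp_d.sum(axis=0), ana_d.sum(axis=0), rtol=0.10)
        # cross-spectra agree in aggregate
        assert (np.linalg.norm(emp.G.mean(axis=0) - ana.G.mean(axis=0))
                < 0.1 * np.linalg.norm(ana.G.mean(axis=0)))
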