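"""Synthetic experiments, weight fitting, goodness of fit, library counting."""

from dataclasses import replace

import numpy as np
import pytest

import hypertab as ht


def protocols(n_uni=15, n_bi=10, uni_end=1.6, bi_end=1.3):
    return [
        ht.LoadingProtocol(mode="uniaxial", start=1.0, end=uni_end, steps=n_uni),
        ht.LoadingProtocol(mode="equibiaxial", start=1.0, end=bi_end, steps=n_bi),
    ]


def free_template(model, w1_rows=(), scale=0.4):
    """Template with every w2 free (perturbed start) and chosen w1 free."""
    rows = [
        replace(r, w2=scale * r.w2 + 0.05, free_w2=True, free_w1=(i in w1_rows))
        for i, r in enumerate(model.rows)
    ]
    return replace(model, rows=rows)


YEOH2 = ht.MaterialModel(
    rows=[ht.ParameterRow(1, 1, 1, 1, w2=1.0), ht.ParameterRow(1, 1, 2, 1, w2=0.3)],
    name="yeoh_two_term",
)


class TestSimulateDataset:
    def test_noiseless_equals_driver_curves(self):
        model = ht.catalog("neo_hooke", C10=1.0)
        proto = ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=11)
        data = ht.simulate_dataset(model, [proto])
        curve = ht.run_protocol(model, proto)
        assert np.array_equal(data.experiments[0].stress[:, 0], curve.data["s11"])

    def test_closed_form_value_present(self):
        model = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            model, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=11)]
        )
        assert data.experiments[0].stress[-1, 0] == pytest.approx(7.0)

    def test_seeded_noise_reproducible(self):
        model = ht.catalog("neo_hooke", C10=1.0)
        a = ht.simulate_dataset(model, protocols(), noise_sd=0.05, seed=7)
        b = ht.simulate_dataset(model, protocols(), noise_sd=0.05, seed=7)
        c = ht.simulate_dataset(model, protocols(), noise_sd=0.05, seed=8)
        for ea, eb in zip(a.experiments, b.experiments):
            assert np.array_equal(ea.stress, eb.stress)
        assert not np.array_equal(a.experiments[0].stress, c.experiments[0].stress)

    def test_multiplicative_noise_scales_with_stress(self):
        model = ht.catalog("neo_hooke", C10=1.0)
        proto = ht.LoadingProtocol(mode="uniaxial", start=1.3, end=2.0, steps=50)
        clean = ht.simulate_dataset(model, [proto]).experiments[0].stress
        noisy = ht.simulate_dataset(
            model, [proto], noise_sd=0.1, seed=0, noise_model="multiplicative"
        ).experiments[0].stress
        rel = np.abs(noisy - clean) / np.abs(clean)
        assert 0.02 < np.median(rel) < 0.3

    def test_nonmonotone_control_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.Experiment(
                protocol=ht.LoadingProtocol(mode="uniaxial"),
                control=np.array([1.0, 1.2, 1.1]),
                F=np.stack([np.eye(3)] * 3),
                stress=np.zeros((3, 1)),
                channels=[(0, 0)],
            )


class TestFitWeights:
    def test_recover_neo_hooke_from_noiseless_uniaxial(self):
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            gen, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=15)]
        )
        fit = ht.fit_weights(free_template(gen), data)
        assert abs(fit.model.rows[0].w2 - 1.0) < 1e-6

    def test_recover_mooney_rivlin_needs_both_protocols(self):
        gen = ht.catalog("mooney_rivlin", C10=0.8, C01=0.4)
        data = ht.simulate_dataset(gen, protocols())
        fit = ht.fit_weights(free_template(gen), data)
        assert fit.model.rows[0].w2 == pytest.approx(0.8, rel=1e-4)
        assert fit.model.rows[1].w2 == pytest.approx(0.4, rel=1e-4)

    def test_recover_valve_fung_inner_weight(self):
        gen = ht.catalog("valve_fung", variant="anterior")
        data = ht.simulate_dataset(gen, protocols(uni_end=1.3, bi_end=1.2))
        tmpl = free_template(gen, w1_rows=(1,))
        tmpl = replace(tmpl, rows=[tmpl.rows[0], replace(tmpl.rows[1], w1=2.0)])
        fit = ht.fit_weights(tmpl, data)
        assert fit.model.rows[0].w2 == pytest.approx(0.5, rel=1e-3)
        assert fit.model.rows[1].w2 == pytest.approx(0.062, rel=1e-3)
        assert fit.model.rows[1].w1 == pytest.approx(4.57, rel=1e-3)

    def test_sparsity_prunes_spurious_terms(self):
        """Strong L1 on neo-Hooke data leaves the I1-linear term dominant."""
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            gen, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=15)]
        )
        tmpl = ht.MaterialModel(
            rows=[
                ht.ParameterRow(1, 1, 1, 1), ht.ParameterRow(1, 1, 2, 1),
                ht.ParameterRow(1, 1, 3, 1), ht.ParameterRow(2, 1, 1, 1),
                ht.ParameterRow(2, 1, 2, 1), ht.ParameterRow(2, 1, 3, 1),
            ]
        )
        fit = ht.fit_weights(tmpl, data, l1_alpha=0.5)
        w = np.array([r.w2 for r in fit.model.rows])
        assert np.argmax(w) == 0
        assert np.all(w[1:] < 0.01 * w[0])

    def test_regularization_path_monotone(self):
        """The count of surviving terms never grows with the L1 strength."""
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            gen, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=2.0, steps=15)]
        )
        tmpl = ht.MaterialModel(
            rows=[
                ht.ParameterRow(1, 1, 1, 1), ht.ParameterRow(1, 1, 2, 1),
                ht.ParameterRow(1, 1, 3, 1), ht.ParameterRow(2, 1, 1, 1),
                ht.ParameterRow(2, 1, 2, 1), ht.ParameterRow(2, 1, 3, 1),
            ]
        )
        counts = []
        for alpha in (0.0, 0.1, 2.0, 50.0, 1e3, 1e4):
            fit = ht.fit_weights(tmpl, data, l1_alpha=alpha)
            counts.append(sum(r.w2 != 0.0 for r in fit.model.rows))
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0  # full shrinkage at the top of the ladder

    def test_objective_log_non_increasing(self):
        gen = ht.catalog("valve_fung", variant="anterior")
        data = ht.simulate_dataset(gen, protocols(uni_end=1.3, bi_end=1.2),
                                   noise_sd=0.01, seed=1)
        tmpl = free_template(gen, w1_rows=(1,))
        fit = ht.fit_weights(tmpl, data, l1_alpha=0.01)
        log = fit.iteration_log
        assert all(b <= a + 1e-12 for a, b in zip(log, log[1:]))

    def test_all_zero_data_with_l1_gives_zero_weights(self):
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            gen, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=1.5, steps=8)]
        )
        for exp in data.experiments:
            exp.stress[:] = 0.0
        fit = ht.fit_weights(free_template(gen), data, l1_alpha=0.1, nonneg=True)
        assert all(r.w2 == 0.0 for r in fit.model.rows)

    def test_empty_data_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.fit_weights(free_template(ht.catalog("neo_hooke")), ht.ExperimentSet([]))


class TestNoisyRecovery:
    @pytest.mark.parametrize(
        "name,gen,w1_rows",
        [
            ("neo_hooke", ht.catalog("neo_hooke", C10=1.0), ()),
            ("mooney_rivlin", ht.catalog("mooney_rivlin", C10=0.8, C01=0.4), ()),
            ("yeoh_two_term", YEOH2, ()),
            ("valve_fung", ht.catalog("valve_fung", variant="anterior"), (1,)),
        ],
        ids=["neo_hooke", "mooney_rivlin", "yeoh2", "valve_fung"],
    )
    def test_median_error_below_ten_percent_over_20_seeds(self, name, gen, w1_rows):
        """noise_sd = 0.02 on ~200 points: median weight error < 10%."""
        protos = protocols(n_uni=100, n_bi=50, uni_end=1.5, bi_end=1.3)
        errs = []
        for seed in range(20):
            data = ht.simulate_dataset(gen, protos, noise_sd=0.02, seed=seed)
            fit = ht.fit_weights(free_template(gen, w1_rows), data)
            rel = max(
                abs(fr.w2 - gr.w2) / abs(gr.w2)
                for fr, gr in zip(fit.model.rows, gen.rows)
            )
            for i in w1_rows:
                rel = max(
                    rel,
                    abs(fit.model.rows[i].w1 - gen.rows[i].w1) / abs(gen.rows[i].w1),
                )
            errs.append(rel)
        assert np.median(errs) < 0.10, errs


class TestRSquared:
    def test_generator_fits_itself_perfectly(self):
        model = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(model, protocols())
        values, mean = ht.r_squared(model, data)
        assert mean == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in values)

    def test_zero_model_can_go_negative(self):
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(gen, protocols())
        zero = ht.catalog("neo_hooke", C10=0.0)
        _, mean = ht.r_squared(zero, data)
        assert mean <= 0.0

    def test_noisy_r2_below_one_and_reproducible(self):
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(gen, protocols(), noise_sd=0.05, seed=11)
        _, m1 = ht.r_squared(gen, data)
        _, m2 = ht.r_squared(gen, data)
        assert m1 == m2 < 1.0

    def test_zero_variance_channel_reported_undefined(self):
        gen = ht.catalog("neo_hooke", C10=1.0)
        data = ht.simulate_dataset(
            gen, [ht.LoadingProtocol(mode="uniaxial", start=1.0, end=1.5, steps=4)]
        )
        data.experiments[0].stress[:] = 5.0  # constant measurement
        values, mean = ht.r_squared(gen, data)
        assert np.isnan(values[0]) and np.isnan(mean)


class TestCountSubmodels:
    @pytest.mark.parametrize("n,expected", [(16, 65536), (32, 4294967296), (0, 1)])
    def test_library_sizes(self, n, expected):
        assert ht.count_submodels(n) == expected

    def test_negative_rejected(self):
        with pytest.raises(ht.ConfigurationError):
            ht.count_submodels(-1)
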