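"""Boundary-model variants: design assembly, OLS fitting, prediction."""

import numpy as np
import pytest

import echolv as e
from echolv.exceptions import MissingAnnotationError
from echolv.models import assemble_design


class TestAssembleDesign:
    def test_column_counts_per_variant(self):
        scores = np.zeros((10, 3))
        phi = np.zeros((10, 8))
        assert assemble_design(scores, phi).shape == (10, 11)
        assert assemble_design(scores, phi, np.zeros(10)).shape == (10, 12)

    def test_assist_column_is_piecewise_constant_per_animal(self):
        cohort = e.generate_model_family_cohort(n_animals=2, frames_per_cycle=12,
                                                image_shape=(6, 6), seed=0)
        # overwrite the assist-anchor truth with known per-animal values
        col = e.anchor_column(e.DEFAULT_ASSIST_ANCHOR)
        cohort[0][1].values[0, col] = 1.5
        cohort[1][1].values[0, col] = 2.0
        model = e.BoundaryRegressor(variant=3, n_components=2, n_basis=4)
        model.fit([s for s, _ in cohort], [t for _, t in cohort])
        mu = model._cache["assist"]
        np.testing.assert_array_equal(mu[:12], 1.5)
        np.testing.assert_array_equal(mu[12:], 2.0)


class TestFitting:
    def test_coefficients_match_normal_equations_oracle(self):
        """OLS on a 20-row fixture vs explicit (X'X)^-1 X'y."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 3))
        from echolv.models import _lstsq

        coef = _lstsq(X, Y)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        np.testing.assert_allclose(coef, oracle, atol=1e-8)

    def test_known_coefficients_recovered_exactly(self):
        """Noiseless data from the model family: beta recovered, residual ~ 0."""
        cohort = e.generate_model_family_cohort(n_animals=6, frames_per_cycle=16,
                                                image_shape=(8, 8), k_true=3, seed=1)
        model = e.BoundaryRegressor(variant=2, n_components=3, n_basis=8)
        model.fit([s for s, _ in cohort], [t for _, t in cohort])
        preds = model.predict([s for s, _ in cohort])
        for (s, truth), pred in zip(cohort, preds):
            np.testing.assert_allclose(pred.values, truth.values, atol=1e-6)

    def test_constant_radii_with_zero_image_signal_predict_the_constant(self):
        F, n = 16, 4
        phases = np.arange(F) / F
        imgs = np.ones((F, 4, 6, 6), dtype=np.float32)
        stacks = [
            e.SliceStack(images=imgs, cycle_phase=phases, animal_id=f"a{i}",
                         apex_z=np.zeros(F), base_z=np.full(F, 5.0),
                         cycle_duration_s=0.12)
            for i in range(n)
        ]
        radii = [e.AnchorRadii(values=np.full((F, 48), 2.5), cycle_phase=phases)
                 for _ in range(n)]
        model = e.BoundaryRegressor(variant=2, n_components=2, n_basis=8)
        model.fit(stacks, radii)
        pred = model.predict([stacks[0]])[0]
        np.testing.assert_allclose(pred.values, 2.5, atol=1e-8)

    def test_training_predictions_reproduce_fitted_values(self):
        cohort = e.generate_model_family_cohort(n_animals=5, frames_per_cycle=12,
                                                image_shape=(6, 6), noise_sd=0.3,
                                                seed=2)
        stacks = [s for s, _ in cohort]
        truths = [t for _, t in cohort]
        model = e.BoundaryRegressor(variant=2, n_components=3, n_basis=6)
        model.fit(stacks, truths)
        pred = np.vstack([p.values for p in model.predict(stacks)])
        scores, phi = model._cache["scores"], model._cache["phi"]
        fitted = assemble_design(scores, phi) @ model.coef_
        np.testing.assert_allclose(pred, fitted, atol=1e-10)

    def test_prediction_invariant_to_unused_components(self):
        cohort = e.generate_model_family_cohort(n_animals=5, frames_per_cycle=12,
                                                image_shape=(6, 6), noise_sd=0.2,
                                                seed=3)
        stacks = [s for s, _ in cohort]
        truths = [t for _, t in cohort]
        big = e.BoundaryRegressor(variant=2, n_components=6, n_basis=6)
        big.fit(stacks, truths)
        small = big.with_components(3)
        direct = e.BoundaryRegressor(variant=2, n_components=3, n_basis=6)
        direct.fit(stacks, truths, image_basis=big.image_basis_)
        p1 = small.predict([stacks[0]])[0].values
        p2 = direct.predict([stacks[0]])[0].values
        np.testing.assert_allclose(p1, p2, atol=1e-9)


class TestVariantThree:
    def make_size_offset_cohort(self, n_animals=8, F=16, seed=0):
        """Animals differ only by scale; images carry no information."""
        rng = np.random.default_rng(seed)
        phases = np.arange(F) / F
        wave = 1.0 - 0.25 * np.asarray(e.contraction_bump(phases, 0.35))
        base = np.linspace(1.8, 3.0, 48)  # per-anchor baseline, epi > endo built in
        base = np.sort(base)
        cohort = []
        for i in range(n_animals):
            scale = rng.uniform(0.8, 1.3)
            values = scale * np.outer(wave, np.ones(48)) * base
            imgs = np.ones((F, 4, 6, 6), dtype=np.float32)
            stack = e.SliceStack(images=imgs, cycle_phase=phases,
                                 animal_id=f"a{i}", apex_z=np.zeros(F),
                                 base_z=np.full(F, 5.0), cycle_duration_s=0.12)
            cohort.append((stack, e.AnchorRadii(values=values, cycle_phase=phases,
                                                validate=False)))
        return cohort

    def test_assist_resolves_pure_size_offsets(self):
        """With uninformative images, only variant 3 can infer animal size."""
        cohort = self.make_size_offset_cohort()
        train, test = cohort[:6], cohort[6:]
        col = e.anchor_column(e.DEFAULT_ASSIST_ANCHOR)

        def mse(variant):
            model = e.BoundaryRegressor(variant=variant, n_components=2, n_basis=8)
            model.fit([s for s, _ in train], [t for _, t in train])
            assists = [t.values[0, col] for _, t in test] if variant == 3 else None
            preds = model.predict([s for s, _ in test], assist_values=assists)
            return np.mean([
                np.mean((p.values - t.values) ** 2)
                for p, (_, t) in zip(preds, test)
            ])

        m2, m3 = mse(2), mse(3)
        assert m3 < m2
        # the assist value carries essentially all animal-specific information
        assert m3 < 0.1 * m2

    def test_missing_annotation_raises(self):
        cohort = self.make_size_offset_cohort(n_animals=4)
        model = e.BoundaryRegressor(variant=3, n_components=2, n_basis=8)
        model.fit([s for s, _ in cohort], [t for _, t in cohort])
        with pytest.raises(MissingAnnotationError):
            model.predict([cohort[0][0]])

    def test_variant3_noiseless_recovery_mse_below_1e6(self):
        cohort = e.generate_model_family_cohort(n_animals=8, frames_per_cycle=16,
                                                image_shape=(8, 8), seed=4)
        train, test = cohort[:6], cohort[6:]
        col = e.anchor_column(e.DEFAULT_ASSIST_ANCHOR)
        model = e.BoundaryRegressor(variant=3, n_components=3, n_basis=8)
        model.fit([s for s, _ in train], [t for _, t in train])
        preds = model.predict([s for s, _ in test],
                              assist_values=[t.values[0, col] for _, t in test])
        mse = np.mean([
            np.mean((p.values - t.values) ** 2) for p, (_, t) in zip(preds, test)
        ])
        assert mse < 1e-6
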