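"""Conditional 1D-GAN: size formulas, architecture chains and training
behavior on tiny problems."""

import numpy as np
import pytest

import ramandx as rx
from ramandx import gan1d, nn
from tests.conftest import toy_peak_set


class TestSizeFormulas:
    @pytest.mark.parametrize(
        "args, expected",
        [((4, 1, 0, 3), 6), ((309, 2, 1, 5), 619), ((1, 1, 0, 1), 1)],
    )
    def test_transposed_conv_sizes(self, args, expected):
        assert rx.transposed_conv_output_size(*args) == expected

    @pytest.mark.parametrize(
        "args, expected",
        [((619, 2, 1, 5), 309), ((6, 1, 0, 6), 1), ((10, 1, 0, 10), 1)],
    )
    def test_conv_sizes(self, args, expected):
        assert rx.conv_output_size(*args) == expected

    def test_non_divisible_conv_rejected(self):
        with pytest.raises(gan1d.ArchitectureError):
            rx.conv_output_size(618, 2, 1, 5)

    def test_non_positive_transposed_rejected(self):
        with pytest.raises(gan1d.ArchitectureError):
            rx.transposed_conv_output_size(1, 1, 2, 1)


class TestArchitectureChains:
    def test_generator_stage_lengths(self):
        specs = rx.GANConfig().generator_layer_specs()
        assert [s.output_size for s in specs] == [6, 25, 77, 309, 619]
        assert [s.n_kernels for s in specs] == [512, 256, 128, 64, 1]

    def test_discriminator_stage_lengths(self):
        specs = rx.GANConfig().discriminator_layer_specs()
        assert [s.output_size for s in specs] == [309, 77, 25, 6, 1]

    def test_wrong_latent_length_rejected(self):
        with pytest.raises(gan1d.ArchitectureError):
            rx.GANConfig(latent_length=5).generator_layer_specs()

    def test_wrong_spectrum_length_rejected(self):
        with pytest.raises(gan1d.ArchitectureError):
            rx.GANConfig(spectrum_length=618).discriminator_layer_specs()

    def test_layer_spec_validates_formula(self):
        with pytest.raises(gan1d.ArchitectureError):
            rx.LayerSpec("transposed_conv", 4, 3, 8, 1, 0, 7)  # formula gives 6

    def test_built_networks_have_advertised_shapes(self):
        cfg = rx.GANConfig(base_width=2, seed=0)
        G, gspecs = rx.build_generator(cfg)
        D, dspecs = rx.build_discriminator(cfg)
        z = np.zeros((3, 1 + 2, 4), dtype=np.float32)
        out = G.forward(z, train=False)
        assert out.shape == (3, 1, 619)
        x = np.zeros((3, 2, 619), dtype=np.float32)
        assert D.forward(x, train=False).shape == (3, 1, 1)
        # BN+ReLU after the first four generator stages only
        kinds = [type(l).__name__ for l in G.layers]
        assert kinds.count("BatchNorm1d") == 4 and kinds[-1] == "ConvTranspose1d"
        dkinds = [type(l).__name__ for l in D.layers]
        assert dkinds.count("LeakyReLU") == 4 and "BatchNorm1d" not in dkinds

    def test_width_scaling_preserves_lengths(self):
        for bw in (2, 8, 64):
            specs = rx.GANConfig(base_width=bw).generator_layer_specs()
            assert [s.output_size for s in specs] == [6, 25, 77, 309, 619]


@pytest.fixture(scope="module")
def trained_toy_gan():
    """A small GAN trained on toy single-bump spectra (module-scoped: the
    training-behavior tests share it)."""
    data = toy_peak_set(n_per_class=100, separation=2.0, noise=0.05, seed=5)
    cfg = rx.GANConfig(base_width=4, epochs=150, seed=2)
    return data, rx.train_gan(data, cfg)


class TestTraining:
    def test_loss_history_length_equals_epochs(self, trained_toy_gan):
        _, state = trained_toy_gan
        assert len(state.generator_loss) == state.cfg.epochs
        assert len(state.discriminator_loss) == state.cfg.epochs
        assert all(np.isfinite(state.generator_loss))

    def test_mean_generated_matches_mean_real_per_class(self, trained_toy_gan):
        data, state = trained_toy_gan
        fake = rx.synthesize_spectra(state, 150, seed=9)
        for cls in (0, 1):
            mr = data.spectra[data.labels == cls].mean(axis=0)
            mf = fake.spectra[fake.labels == cls].mean(axis=0)
            r = np.corrcoef(mr, mf)[0, 1]
            assert r > 0.8, f"class {cls} mean correlation {r:.2f}"

    def test_conditioning_label_recovered_by_real_data_classifier(self):
        """A classifier trained on real toy data assigns generated spectra
        to their conditioning label (median over 3 training seeds)."""
        from sklearn.linear_model import LogisticRegression

        data = toy_peak_set(n_per_class=100, separation=2.0, noise=0.05, seed=5)
        clf = LogisticRegression(max_iter=1000).fit(data.spectra, data.labels)
        accs = []
        for seed in (3, 4, 5):
            state = rx.train_gan(data, rx.GANConfig(base_width=4, epochs=150, seed=seed))
            fake = rx.synthesize_spectra(state, 150, seed=11)
            accs.append(float(np.mean(clf.predict(fake.spectra) == fake.labels)))
        assert float(np.median(accs)) > 0.7

    def test_untrained_generator_uncorrelated_with_real_structure(self):
        """With zero epochs the generator's learned deviation from the
        training mean is noise: per-class deviations of generated and real
        spectra are uncorrelated (compared in standardized space, since
        de-standardization re-adds the real mean by construction)."""
        data = toy_peak_set(n_per_class=30, seed=6)
        cfg = rx.GANConfig(base_width=2, epochs=0, seed=3)
        state = rx.train_gan(data, cfg)
        assert state.generator_loss == []
        fake = rx.synthesize_spectra(state, 50, seed=1)
        real_dev = data.spectra[data.labels == 1].mean(0) - state.mean_spectrum
        fake_dev = fake.spectra[fake.labels == 1].mean(0) - state.mean_spectrum
        r = np.corrcoef(real_dev, fake_dev)[0, 1]
        assert abs(r) < 0.5

    def test_single_class_training_rejected(self, axis):
        ds = rx.LabeledSpectrumSet(axis, np.ones((10, axis.n_points)), np.zeros(10))
        with pytest.raises(Exception):
            rx.train_gan(ds, rx.GANConfig(base_width=2, epochs=1))


class TestSynthesize:
    def test_counts_and_balance(self, trained_toy_gan):
        _, state = trained_toy_gan
        out = rx.synthesize_spectra(state, 25, seed=0)
        assert out.n == 50
        assert out.class_counts() == (25, 25)
        assert set(out.provenance) == {"gan"}
        assert out.spectra.shape[1] == 619

    def test_zero_request_gives_empty_set(self, trained_toy_gan):
        _, state = trained_toy_gan
        assert rx.synthesize_spectra(state, 0, seed=0).n == 0

    def test_deterministic_under_seed(self, trained_toy_gan):
        _, state = trained_toy_gan
        a = rx.synthesize_spectra(state, 10, seed=4)
        b = rx.synthesize_spectra(state, 10, seed=4)
        np.testing.assert_array_equal(a.spectra, b.spectra)
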