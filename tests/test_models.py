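"""Architecture contracts: loss composition, sparsity, determinism,
gradient gating and trainability (overfit-one-batch)."""

import numpy as np
import pytest

from radiosurv.autodiff import Tensor
from radiosurv.datatypes import SurvivalLabels
from radiosurv.losses import (
    capacity_regularizer,
    cox_neg_log_partial_likelihood,
    l2_penalty,
)
from radiosurv.models import (
    BaselineVAECoxSpec,
    GeneSparseAECoxSpec,
    HVAECoxSpec,
    ImageAECoxSpec,
    TrainConfig,
    XATVAECoxSpec,
    _run_schedule,
    fit_gene_ae,
    fit_hvae,
    fit_image_ae,
    fit_xat,
)
from radiosurv.preprocess import build_pathway_mask
from radiosurv.simulate import SyntheticConfig, generate_dataset


SMALL = dict(n_samples=16, image_size=(16, 16), n_genes=12, n_pathways=3,
             genes_per_pathway=4, n_active_pathways=2,
             beta_pathway=(0.8, 0.8), radius_range=(2.0, 4.0),
             beta_clinical=(0.3, -0.3, 0.0, 0.0, 0.0, 0.0))


@pytest.fixture(scope="module")
def tiny():
    ds, gt = generate_dataset(SyntheticConfig(seed=42, **SMALL))
    mask = build_pathway_mask(gt.pathways, ds.expression.gene_ids)
    expr = ds.expression.values
    expr = (expr - expr.mean(0)) / (expr.std(0) + 1e-8)
    clin = ds.clinical.values
    arrays = {"images": ds.images.values, "expression": expr,
              "clinical": (clin - clin.mean(0)) / (clin.std(0) + 1e-8)}
    return ds, gt, mask, arrays


def tiny_specs(arrays):
    size = arrays["images"].shape[1:]
    return {
        "gene": GeneSparseAECoxSpec(latent_dim=4, cox_hidden=(4,)),
        "image": ImageAECoxSpec(channels=(2, 4), latent_dim=4,
                                cox_hidden=(4,), input_size=size),
        "xat": XATVAECoxSpec(channels=(2, 4), latent_dim=6,
                             input_size=size, detach_cox_input=True),
        "baseline": BaselineVAECoxSpec(channels=(2, 4), latent_dim=6,
                                       input_size=size,
                                       detach_cox_input=True),
    }


class TestLossComposition:
    def test_gene_total_is_sum_of_terms(self, tiny):
        ds, gt, mask, arrays = tiny
        cfg = TrainConfig(epochs=2, seed=0)
        model = fit_gene_ae(arrays["expression"], ds.labels, mask,
                            tiny_specs(arrays)["gene"], cfg)
        out = model.forward_t(arrays["expression"])
        total, parts = model.loss_t(out, arrays["expression"], ds.labels, cfg)
        assert float(total.data) == pytest.approx(
            sum(float(p.data) for p in parts.values()), rel=1e-10)
        # cross-check the terms against the public numpy losses
        n_events = ds.labels.event.sum()
        assert float(parts["cox"].data) * n_events == pytest.approx(
            cox_neg_log_partial_likelihood(out["pi"].data, ds.labels),
            rel=1e-10)
        assert float(parts["l2"].data) == pytest.approx(
            l2_penalty([p.data for p in model.cox.parameters()],
                       cfg.l2_lam), rel=1e-10)

    def test_xat_total_is_weighted_sum(self, tiny):
        ds, gt, mask, arrays = tiny
        cfg = TrainConfig(epochs=2, seed=0, Kvl=0.7, Kcl=2.0)
        model = fit_xat(arrays, ds.labels, mask, tiny_specs(arrays)["xat"],
                        cfg)
        out = model.forward_t(arrays["images"], arrays["expression"],
                              arrays["clinical"])
        total, parts = model.loss_t(out, arrays["images"],
                                    arrays["expression"], ds.labels, 5, cfg)
        expected = (0.7 * float(parts["xvae"].data)
                    + 2.0 * (float(parts["cox"].data)
                             + float(parts["l2"].data)))
        assert float(total.data) == pytest.approx(expected, rel=1e-10)
        # KL regularizer equals the scalar schedule formula
        assert float(parts["kl_reg"].data) == pytest.approx(
            capacity_regularizer(float(out["kl"].data), 5,
                                 _run_schedule(cfg)), rel=1e-10)


class TestSparsityContract:
    def test_masked_weights_zero_after_training(self, tiny):
        ds, gt, mask, arrays = tiny
        model = fit_gene_ae(arrays["expression"], ds.labels, mask,
                            tiny_specs(arrays)["gene"],
                            TrainConfig(epochs=30, seed=1))
        A = mask.matrix
        assert np.all(model.sparse.W.data[A == 0] == 0.0)
        assert np.all(model.dec_genes.W.data[A.T == 0] == 0.0)

    def test_perturbing_masked_weights_is_invisible(self, tiny):
        ds, gt, mask, arrays = tiny
        model = fit_gene_ae(arrays["expression"], ds.labels, mask,
                            tiny_specs(arrays)["gene"],
                            TrainConfig(epochs=5, seed=1))
        base = model.predict_pi(arrays["expression"])
        A = mask.matrix
        model.sparse.W.data = model.sparse.W.data + (1 - A) * 123.0
        assert np.array_equal(model.predict_pi(arrays["expression"]), base)


class TestInferenceDeterminism:
    @pytest.mark.parametrize("which", ["gene", "image", "xat"])
    def test_repeated_predictions_bit_identical(self, tiny, which):
        ds, gt, mask, arrays = tiny
        cfg = TrainConfig(epochs=3, seed=2)
        specs = tiny_specs(arrays)
        if which == "gene":
            model = fit_gene_ae(arrays["expression"], ds.labels, mask,
                                specs["gene"], cfg)
            pred = lambda: model.predict_pi(arrays["expression"])
        elif which == "image":
            model = fit_image_ae(arrays["images"], ds.labels,
                                 specs["image"], cfg)
            pred = lambda: model.predict_pi(arrays["images"])
        else:
            model = fit_xat(arrays, ds.labels, mask, specs["xat"], cfg)
            pred = lambda: model.predict_pi(images=arrays["images"],
                                            expr=arrays["expression"],
                                            clinical=arrays["clinical"])
        assert np.array_equal(pred(), pred())

    def test_permuting_samples_permutes_pi(self, tiny):
        ds, gt, mask, arrays = tiny
        model = fit_xat(arrays, ds.labels, mask, tiny_specs(arrays)["xat"],
                        TrainConfig(epochs=3, seed=2))
        pi = model.predict_pi(images=arrays["images"],
                              expr=arrays["expression"],
                              clinical=arrays["clinical"])
        perm = np.random.default_rng(0).permutation(len(pi))
        pi_perm = model.predict_pi(images=arrays["images"][perm],
                                   expr=arrays["expression"][perm],
                                   clinical=arrays["clinical"][perm])
        assert np.allclose(pi_perm, pi[perm])


class TestGradientGating:
    def test_kcl_zero_gives_no_cox_head_gradient(self, tiny):
        ds, gt, mask, arrays = tiny
        cfg = TrainConfig(epochs=1, seed=0, Kcl=0.0)
        model = fit_xat(arrays, ds.labels, mask, tiny_specs(arrays)["xat"],
                        TrainConfig(epochs=1, seed=0))
        model.zero_grad()
        out = model.forward_t(arrays["images"], arrays["expression"],
                              arrays["clinical"],
                              noise=np.zeros((16, 6)))
        total, _ = model.loss_t(out, arrays["images"], arrays["expression"],
                                ds.labels, 0, cfg)
        total.backward()
        for p in model.cox.parameters():
            assert p.grad is None or np.all(p.grad == 0.0)

    def test_kvl_zero_gives_no_decoder_gradient(self, tiny):
        ds, gt, mask, arrays = tiny
        cfg = TrainConfig(epochs=1, seed=0, Kvl=0.0)
        model = fit_xat(arrays, ds.labels, mask, tiny_specs(arrays)["xat"],
                        TrainConfig(epochs=1, seed=0))
        model.zero_grad()
        out = model.forward_t(arrays["images"], arrays["expression"],
                              arrays["clinical"],
                              noise=np.zeros((16, 6)))
        total, _ = model.loss_t(out, arrays["images"], arrays["expression"],
                                ds.labels, 0, cfg)
        total.backward()
        for layer in (model.dec_img1, model.dec_img2, model.dec_gene_out):
            for p in layer.parameters():
                assert p.grad is None or np.all(p.grad == 0.0)


class TestHVAEContract:
    def test_bundle_rejects_missing_modality(self, tiny):
        ds, gt, mask, arrays = tiny
        specs = tiny_specs(arrays)
        cfg = TrainConfig(epochs=2, seed=0)
        gm = fit_gene_ae(arrays["expression"], ds.labels, mask,
                         specs["gene"], cfg)
        im = fit_image_ae(arrays["images"], ds.labels, specs["image"], cfg)
        bundle = fit_hvae(arrays, ds.labels, gm, im,
                          HVAECoxSpec(latent_dim=8), cfg)
        with pytest.raises(ValueError, match="expression"):
            bundle.predict_pi(images=arrays["images"],
                              clinical=arrays["clinical"])

    def test_bypass_reduces_to_cox_mlp_on_codes(self, tiny):
        from radiosurv.models import HVAECox
        ds, gt, mask, arrays = tiny
        rng = np.random.default_rng(0)
        high = HVAECox(6, 6, HVAECoxSpec(latent_dim=6), rng,
                       bypass_encoder=True)
        z = rng.standard_normal((16, 6))
        out = high.forward_t(z, arrays["clinical"])
        assert np.array_equal(out["mu"].data, z)
        assert out["kl"] is None

    def test_low_level_encoders_frozen_in_step3(self, tiny):
        ds, gt, mask, arrays = tiny
        specs = tiny_specs(arrays)
        cfg = TrainConfig(epochs=4, seed=0)
        gm = fit_gene_ae(arrays["expression"], ds.labels, mask,
                         specs["gene"], cfg)
        im = fit_image_ae(arrays["images"], ds.labels, specs["image"], cfg)
        w_before = gm.sparse.W.data.copy()
        conv_before = im.enc1.W.data.copy()
        fit_hvae(arrays, ds.labels, gm, im, HVAECoxSpec(latent_dim=8), cfg)
        assert np.array_equal(gm.sparse.W.data, w_before)
        assert np.array_equal(im.enc1.W.data, conv_before)


class TestParameterCounts:
    def test_baseline_gene_branch_denser_than_masked(self, tiny):
        ds, gt, mask, arrays = tiny
        specs = tiny_specs(arrays)
        cfg = TrainConfig(epochs=1, seed=0)
        xat = fit_xat(arrays, ds.labels, mask, specs["xat"], cfg)
        base = fit_xat(arrays, ds.labels, mask, specs["baseline"], cfg)
        assert base.gene_branch_param_count() > \
            xat.gene_branch_param_count(effective=True)


class TestOverfitOneBatch:
    """Every architecture can drive its training loss sharply down on a
    tiny batch — no silently broken gradients."""

    @pytest.mark.parametrize("which", ["gene", "image", "xat", "baseline"])
    def test_loss_decreases_strongly(self, tiny, which):
        ds, gt, mask, arrays = tiny
        idx = np.arange(8)
        sub = {k: v[idx] for k, v in arrays.items()}
        labels = ds.labels.subset(idx)
        specs = tiny_specs(arrays)
        cfg = TrainConfig(epochs=250, seed=3, lr=2e-2, dropout=0.0)
        if which == "gene":
            model = fit_gene_ae(sub["expression"], labels, mask,
                                specs["gene"], cfg)
        elif which == "image":
            model = fit_image_ae(sub["images"], labels, specs["image"], cfg)
        else:
            model = fit_xat(sub, labels, mask, specs[which], cfg)
        history = model.history
        assert history[-1] < 0.5 * history[0]

    def test_image_reconstruction_of_constant_batch(self, tiny):
        ds, gt, mask, arrays = tiny
        const = np.full((6, 16, 16), 0.25)
        labels = SurvivalLabels(np.arange(1.0, 7.0), np.ones(6, dtype=int))
        model = fit_image_ae(const, labels,
                             ImageAECoxSpec(channels=(2, 4), latent_dim=4,
                                            cox_hidden=(4,),
                                            input_size=(16, 16)),
                             TrainConfig(epochs=150, seed=0, lr=1e-2))
        recon = model.forward(const).reconstructions["images"]
        assert np.mean((recon - const) ** 2) < 1e-3


def test_out_of_range_images_warn_and_clip(tiny):
    ds, gt, mask, arrays = tiny
    bad = arrays["images"].copy() * 1.5
    with pytest.warns(UserWarning, match="clip"):
        fit_image_ae(bad, ds.labels,
                     ImageAECoxSpec(channels=(2, 4), latent_dim=4,
                                    cox_hidden=(4,), input_size=(16, 16)),
                     TrainConfig(epochs=1, seed=0))
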