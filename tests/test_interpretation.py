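"""Attribution correctness: expected gradients, modality scores,
Grad-CAM and gene ranking."""

import numpy as np
import pytest

from radiosurv.interpret import (
    AttributionSet,
    completeness_gap,
    decode_latent_attributions,
    export_rnk,
    grad_cam,
    gradient_attributions,
    high_risk_subset,
    modality_contribution,
    rank_genes_by_attribution,
)


class TestHighRiskSubset:
    def test_above_median_selected(self):
        pi = np.array([1.0, 2.0, 3.0, 4.0])
        groups = (pi > np.median(pi)).astype(int)
        assert high_risk_subset(pi, groups).tolist() == [2, 3]

    def test_empty_high_group_errors(self):
        with pytest.raises(ValueError):
            high_risk_subset(np.ones(3), np.zeros(3, dtype=int))


def linear_grad_fn(weights):
    """PI = sum_m x_m . w_m over modalities (exact linear model)."""

    def fn(**inputs):
        pi = sum(inputs[k].reshape(len(inputs[k]), -1) @
                 weights[k].ravel() for k in inputs)
        grads = {k: np.broadcast_to(weights[k], inputs[k].shape).copy()
                 for k in inputs}
        return pi, grads

    return fn


class TestGradientAttributions:
    def test_linear_model_closed_form(self, rng):
        w = {"gene": rng.standard_normal(5)}
        x = rng.standard_normal((4, 5))
        b = rng.standard_normal(5)
        attrs = gradient_attributions(linear_grad_fn(w), {"gene": x},
                                      baseline={"gene": b}, n_steps=8)
        expected = (x - b) * w["gene"]
        assert np.allclose(attrs["gene"], expected, atol=1e-10)

    def test_sample_equal_to_baseline_gives_zero(self, rng):
        w = {"gene": rng.standard_normal(3), "image": rng.standard_normal(4)}
        b = {"gene": rng.standard_normal(3), "image": rng.standard_normal(4)}
        samples = {k: np.tile(v, (2, 1)) for k, v in b.items()}
        attrs = gradient_attributions(linear_grad_fn(w), samples,
                                      baseline=b, n_steps=4)
        for k in attrs.modalities():
            assert np.allclose(attrs[k], 0.0)

    def test_completeness_on_trained_model(self):
        # small trained fusion model: sum of attributions matches
        # PI(x) - PI(baseline) within 5%
        from radiosurv.interpret import multimodal_grad_fn
        from radiosurv.models import TrainConfig, XATVAECoxSpec, fit_xat
        from radiosurv.preprocess import build_pathway_mask
        from radiosurv.simulate import SyntheticConfig, generate_dataset

        ds, gt = generate_dataset(SyntheticConfig(
            n_samples=16, image_size=(16, 16), n_genes=12, n_pathways=3,
            genes_per_pathway=4, n_active_pathways=2,
            beta_pathway=(0.8, 0.8), radius_range=(2.0, 4.0),
            beta_clinical=(0.3, -0.3, 0, 0, 0, 0), seed=3))
        mask = build_pathway_mask(gt.pathways, ds.expression.gene_ids)
        expr = ds.expression.values
        expr = (expr - expr.mean(0)) / (expr.std(0) + 1e-8)
        arrays = {"images": ds.images.values, "expression": expr,
                  "clinical": ds.clinical.values}
        model = fit_xat(arrays, ds.labels, mask,
                        XATVAECoxSpec(channels=(2, 4), latent_dim=6,
                                      input_size=(16, 16),
                                      detach_cox_input=True),
                        TrainConfig(epochs=30, seed=0))
        samples = {"image": arrays["images"], "gene": expr,
                   "clinical": arrays["clinical"]}
        baseline = {k: v.mean(axis=0) for k, v in samples.items()}
        attrs = gradient_attributions(multimodal_grad_fn(model), samples,
                                      baseline=baseline, n_steps=64)
        pi = model.predict_pi(images=arrays["images"], expr=expr,
                              clinical=arrays["clinical"])
        pi_base = model.predict_pi(images=baseline["image"][None],
                                   expr=baseline["gene"][None],
                                   clinical=baseline["clinical"][None])[0]
        gap = completeness_gap(attrs, pi, pi_base)
        scale = np.abs(pi - pi_base).mean()
        assert gap < 0.05 * scale + 1e-6


class TestModalityContribution:
    def test_simple_proportions(self):
        attrs = AttributionSet({"image": np.array([[2.0]]),
                                "gene": np.array([[1.0]]),
                                "clinical": np.array([[1.0]])})
        scores = modality_contribution(attrs)
        assert scores.scores == {"image": 0.5, "gene": 0.25,
                                 "clinical": 0.25}

    def test_single_nonzero_modality(self):
        attrs = AttributionSet({"image": np.array([[0.0]]),
                                "gene": np.array([[3.0]]),
                                "clinical": np.array([[0.0]])})
        scores = modality_contribution(attrs)
        assert scores.scores["gene"] == 1.0
        assert scores.scores["image"] == 0.0

    def test_absolute_sum_arithmetic(self):
        attrs = AttributionSet({"image": np.array([[1.0, -1.0]]),
                                "gene": np.array([[0.5]]),
                                "clinical": np.array([[0.5]])})
        scores = modality_contribution(attrs)
        assert scores.phi == {"image": 2.0, "gene": 0.5, "clinical": 0.5}
        assert scores.scores["image"] == pytest.approx(2 / 3)
        assert sum(scores.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_errors(self):
        attrs = AttributionSet({"gene": np.zeros((2, 3))})
        with pytest.raises(ValueError):
            modality_contribution(attrs)


class _FakeConvModel:
    """Exposes gradcam_maps with prescribed activations/gradients."""

    def __init__(self, f, g):
        self.f, self.g = f, g

    def gradcam_maps(self, images, layer="conv2"):
        if layer != "conv2":
            raise ValueError("layer not found; available: ['conv2']")
        return self.f, self.g


class TestGradCam:
    def test_single_map_uniform_gradient_proportional(self, rng):
        f = np.abs(rng.standard_normal((1, 1, 4, 4)))
        g = np.ones_like(f) * 0.7
        maps = grad_cam(_FakeConvModel(f, g), np.zeros((1, 8, 8)))
        heat = maps[0].heatmap
        # proportional to the (upsampled) activation map
        from skimage.transform import resize
        up = resize(0.7 * f[0, 0], (8, 8), order=1, mode="edge",
                    preserve_range=True, anti_aliasing=False)
        assert np.allclose(heat, np.maximum(up, 0.0))

    def test_negative_gradients_give_zero_map(self, rng):
        f = np.abs(rng.standard_normal((2, 3, 4, 4)))
        g = -np.abs(rng.standard_normal((2, 3, 4, 4)))
        maps = grad_cam(_FakeConvModel(f, g), np.zeros((2, 8, 8)))
        for m in maps:
            assert np.all(m.heatmap == 0.0)

    def test_nonnegative_everywhere(self, rng):
        f = rng.standard_normal((3, 4, 8, 8))
        g = rng.standard_normal((3, 4, 8, 8))
        maps = grad_cam(_FakeConvModel(f, g), np.zeros((3, 16, 16)))
        for m in maps:
            assert m.heatmap.min() >= 0.0

    def test_unknown_layer_lists_available(self):
        model = _FakeConvModel(np.zeros((1, 1, 2, 2)),
                               np.zeros((1, 1, 2, 2)))
        with pytest.raises(ValueError, match="available"):
            grad_cam(model, np.zeros((1, 4, 4)), layer="conv9")


class TestDecodeLatentAttributions:
    def test_identity_decoder_preserves_attribution(self, rng):
        attr = rng.standard_normal((2, 5))
        out = decode_latent_attributions(attr, lambda z: z)
        assert np.allclose(out, attr)

    def test_zero_attribution_maps_to_zero(self, rng):
        W = rng.standard_normal((4, 6))
        b = rng.standard_normal(6)
        out = decode_latent_attributions(np.zeros((1, 4)),
                                         lambda z: z @ W + b)
        assert np.allclose(out, 0.0)

    def test_sign_preserved_through_linear_decoder(self):
        W = np.array([[2.0, -1.0]])
        out = decode_latent_attributions(np.array([[1.0]]),
                                         lambda z: z @ W + 5.0)
        assert out[0, 0] > 0 and out[0, 1] < 0


class TestGeneRanking:
    def _attrs(self, matrix):
        return AttributionSet({"gene": np.asarray(matrix, dtype=float)})

    def test_dominant_gene_first(self):
        attrs = self._attrs([[0.1, 5.0, 0.2], [0.2, -4.0, 0.1]])
        ranked = rank_genes_by_attribution(attrs, ["a", "b", "c"])
        assert ranked[0][0] == "b"

    def test_scale_invariance_of_order(self, rng):
        phi = rng.standard_normal((4, 6))
        genes = [f"g{i}" for i in range(6)]
        base = [g for g, _ in rank_genes_by_attribution(self._attrs(phi),
                                                        genes)]
        scaled = [g for g, _ in rank_genes_by_attribution(
            self._attrs(phi * 17.0), genes)]
        assert base == scaled

    def test_top_fraction_floor_cut(self):
        phi = np.ones((1, 11))
        ranked = rank_genes_by_attribution(
            self._attrs(phi), [f"g{i:02d}" for i in range(11)],
            top_fraction=0.15)
        assert len(ranked) == 1   # floor(11 * 0.15)

    def test_tie_break_on_gene_id(self):
        phi = np.ones((1, 3))
        ranked = rank_genes_by_attribution(self._attrs(phi),
                                           ["z", "a", "m"], top_k=3)
        assert [g for g, _ in ranked] == ["a", "m", "z"]

    def test_k_exceeding_gene_count_errors(self):
        with pytest.raises(ValueError):
            rank_genes_by_attribution(self._attrs(np.ones((1, 2))),
                                      ["a", "b"], top_k=3)

    def test_rnk_export_round_trip(self, tmp_path):
        ranked = [("gA", 0.5), ("gB", -0.25)]
        path = tmp_path / "genes.rnk"
        export_rnk(ranked, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == ["gA", "0.5"]
        assert lines[1].split("\t")[0] == "gB"
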