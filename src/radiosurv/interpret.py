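"""Attribution of the prognostic index to inputs.

Feature attributions are expected gradients (path-integrated gradients
averaged over baseline draws): for input x, baseline b and PI(.),

    phi_j = (x_j - b_j) * mean_alpha dPI/dx_j (b + alpha (x - b))

which satisfies completeness, sum_j phi_j ~ PI(x) - PI(b), and reduces
to w_j (x_j - b_j) exactly for a linear PI. Modality contributions are
absolute attribution sums, normalized to multimodality scores that add
to one. Grad-CAM heatmaps localize the image evidence; gene
attributions are ranked and exportable for external enrichment tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

MODALITIES = ("image", "gene", "clinical")


@dataclass
class AttributionSet:
    """Signed attributions per modality, one row per attributed sample."""

    values: dict   # modality name -> array (n_samples, *feature_shape)

    def __post_init__(self):
        for name, arr in self.values.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite attributions for {name!r}")

    def __getitem__(self, key):
        return self.values[key]

    def modalities(self):
        return list(self.values)


@dataclass
class ModalityAttribution:
    """Absolute attribution mass and normalized multimodality scores."""

    phi: dict      # modality -> nonnegative total |phi|
    scores: dict   # modality -> share in [0, 1]; sums to 1


@dataclass
class GradCamMap:
    heatmap: np.ndarray   # (H, W) nonnegative, input resolution
    layer: str

    def __post_init__(self):
        if np.any(self.heatmap < 0) or not np.all(np.isfinite(self.heatmap)):
            raise ValueError("Grad-CAM heatmap must be finite and >= 0")


def high_risk_subset(pi, groups) -> np.ndarray:
    """Indices of the high-risk group (from median stratification)."""
    groups = np.asarray(groups)
    idx = np.nonzero(groups == 1)[0]
    if len(idx) == 0:
        raise ValueError("no high-risk samples (empty high group)")
    return idx


def gradient_attributions(grad_fn, samples: dict, baseline: dict | None = None,
                          n_steps: int = 64, seed: int = 0) -> AttributionSet:
    """Expected-gradients attribution of PI to each input feature.

    Parameters
    ----------
    grad_fn
        Callable mapping modality arrays to ``(pi, grads)`` where grads
        is a dict of arrays shaped like the inputs (e.g. a model's
        ``input_gradients`` method, or a wrapper for single-modality
        models).
    samples
        Modality name -> array of the samples to attribute.
    baseline
        Modality name -> reference array broadcastable to one sample;
        defaults to the mean over ``samples``.
    n_steps
        Number of interpolation points on the straight path.
    """
    names = list(samples)
    samples = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    n = len(samples[names[0]])
    if baseline is None:
        baseline = {k: v.mean(axis=0) for k, v in samples.items()}
    baseline = {k: np.asarray(baseline[k], dtype=float) for k in names}
    rng = np.random.default_rng(seed)
    # midpoint rule with a small seeded jitter shared across samples
    alphas = (np.arange(n_steps) + rng.uniform(0, 1, n_steps)) / n_steps
    totals = {k: np.zeros_like(samples[k]) for k in names}
    for alpha in alphas:
        point = {k: baseline[k][None] + alpha * (samples[k] - baseline[k][None])
                 for k in names}
        _, grads = grad_fn(**point)
        for k in names:
            totals[k] += grads[k]
    attrs = {k: (samples[k] - baseline[k][None]) * totals[k] / n_steps
             for k in names}
    return AttributionSet(attrs)


def completeness_gap(attrs: AttributionSet, pi_samples, pi_baseline) -> float:
    """|sum phi - (mean PI(x) - PI(b))| summed over samples (diagnostic)."""
    total = sum(attrs[k].reshape(len(attrs[k]), -1).sum(axis=1)
                for k in attrs.modalities())
    return float(np.abs(total - (np.asarray(pi_samples) - pi_baseline)).mean())


def decode_latent_attributions(latent_attrs, decoder_fn) -> np.ndarray:
    """Map latent-space attributions to input space through a decoder.

    The decoder output at the zero-attribution reference is subtracted,
    so zero latent attribution maps to zero importance while the sign
    of the decoded difference is preserved.
    """
    latent_attrs = np.atleast_2d(np.asarray(latent_attrs, dtype=float))
    decoded = decoder_fn(latent_attrs)
    reference = decoder_fn(np.zeros_like(latent_attrs[:1]))
    return decoded - reference


def modality_contribution(attrs: AttributionSet) -> ModalityAttribution:
    """Absolute attribution mass per modality and normalized scores."""
    phi = {k: float(np.abs(attrs[k]).sum()) for k in attrs.modalities()}
    total = sum(phi.values())
    if total == 0:
        raise ValueError("all attributions are zero; scores undefined")
    scores = {k: v / total for k, v in phi.items()}
    return ModalityAttribution(phi, scores)


def grad_cam(model, images, expr=None, clinical=None,
             layer: str = "conv2") -> list[GradCamMap]:
    """Gradient-weighted class-activation maps of the PI.

    ``model`` must expose ``gradcam_maps(...)`` returning the selected
    layer's activation maps and the PI gradients w.r.t. them. Channel
    weights are the spatially averaged gradients; the heatmap is the
    ReLU of the weighted activation sum, upsampled to input resolution.
    """
    images = np.asarray(images, dtype=float)
    if expr is None and clinical is None:
        f, g = model.gradcam_maps(images, layer=layer)
    else:
        f, g = model.gradcam_maps(images, expr, clinical, layer=layer)
    if g is None:
        g = np.zeros_like(f)
    alpha = g.mean(axis=(2, 3))                       # (n, C)
    heat = np.einsum("nc,nchw->nhw", alpha, f)
    heat = np.maximum(heat, 0.0)
    H, W = images.shape[1:]
    maps = []
    for h in heat:
        up = resize(h, (H, W), order=1, mode="edge", preserve_range=True,
                    anti_aliasing=False)
        maps.append(GradCamMap(np.maximum(up, 0.0), layer))
    return maps


def rank_genes_by_attribution(attrs: AttributionSet, gene_ids,
                              top_k: int | None = None,
                              top_fraction: float | None = None,
                              statistic: str = "mean_abs"):
    """Rank genes by attribution across high-risk samples.

    ``statistic``: ``mean_abs`` (default) or ``mean_signed``. The cut is
    ``top_k`` genes or ``floor(m * top_fraction)``; ties break on gene
    id for determinism. Returns a list of ``(gene_id, score)`` pairs in
    rank order.
    """
    gene_ids = [str(g) for g in gene_ids]
    phi = np.asarray(attrs["gene"], dtype=float)
    if phi.shape[1] != len(gene_ids):
        raise ValueError("gene attribution width does not match gene_ids")
    if statistic == "mean_abs":
        score = np.abs(phi).mean(axis=0)
    elif statistic == "mean_signed":
        score = phi.mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    m = len(gene_ids)
    if top_k is None:
        top_k = m if top_fraction is None else int(np.floor(m * top_fraction))
    if top_k > m:
        raise ValueError(f"top_k ({top_k}) exceeds gene count ({m})")
    order = sorted(range(m), key=lambda i: (-score[i], gene_ids[i]))
    return [(gene_ids[i], float(score[i])) for i in order[:top_k]]


def export_rnk(ranked, path) -> None:
    """Write a GSEA-compatible .rnk file (gene_id TAB score)."""
    with open(path, "w") as fh:
        for gene, score in ranked:
            fh.write(f"{gene}\t{score:.6g}\n")


def multimodal_grad_fn(model):
    """Adapt a fusion model's ``input_gradients`` to the grad_fn protocol."""

    def fn(image, gene, clinical):
        return model.input_gradients(image, gene, clinical)

    return fn


def single_modality_grad_fn(model, modality: str):
    """Adapt a single-modality model to the multi-input grad_fn protocol."""
    key = {"image": "image", "gene": "gene"}[modality]

    def fn(**inputs):
        arr = inputs[modality]
        pi, grads = model.input_gradients(arr)
        return pi, {modality: grads[key]}

    return fn
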