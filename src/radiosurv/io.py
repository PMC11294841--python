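"""Readers and writers for the on-disk dataset formats.

Tabular inputs are delimited text: first column sample id, header row of
feature ids, ``NA`` or empty cells marking missing values. Pathway gene
sets use the GMT dialect (name, description, then genes, tab-separated).
Image stacks live either in a single ``.npz`` archive or as one raster
file per sample.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    ImageStack,
    PathwaySet,
    RadiogenomicsDataset,
    SurvivalLabels,
)


class GMTParseError(ValueError):
    pass


def read_gmt(path) -> PathwaySet:
    """Parse a GMT file into a :class:`PathwaySet`.

    Each line must carry at least three tab-separated fields:
    name, description, and one or more gene ids. Duplicate genes within
    a set are removed (first occurrence kept).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GMTParseError(
                    f"{path}: line {lineno}: expected name, description and "
                    f">=1 gene, got {len(fields)} field(s)")
            name, _desc, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise GMTParseError(f"{path}: line {lineno}: no genes listed")
            sets[name] = list(dict.fromkeys(genes))
    return PathwaySet(sets)


def write_gmt(sets: PathwaySet, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets.names:
            fh.write("\t".join([name, description, *sets[name]]) + "\n")


def _read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0,
                     na_values=["NA", ""])
    df.index = df.index.astype(str)
    return df


def read_expression(path, allow_missing: bool = True) -> ExpressionMatrix:
    df = _read_table(path)
    return ExpressionMatrix(df.to_numpy(dtype=float), list(df.columns),
                            list(df.index), allow_missing=allow_missing)


def write_expression(expr: ExpressionMatrix, path) -> None:
    pd.DataFrame(expr.values, index=expr.sample_ids,
                 columns=expr.gene_ids).to_csv(path, sep="\t", na_rep="NA")


def read_clinical(path) -> ClinicalTable:
    df = _read_table(path)
    return ClinicalTable(df.to_numpy(dtype=float), list(df.columns),
                         list(df.index))


def write_clinical(clin: ClinicalTable, path) -> None:
    pd.DataFrame(clin.values, index=clin.sample_ids,
                 columns=clin.feature_names).to_csv(path, sep="\t")


def read_survival(path) -> tuple[list[str], SurvivalLabels]:
    """Read a survival table with columns sample_id, time, event."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    for required in ("sample_id", "time", "event"):
        if required not in cols:
            raise ValueError(f"survival table missing column {required!r}")
    ids = [str(s) for s in df[cols["sample_id"]]]
    return ids, SurvivalLabels(df[cols["time"]].to_numpy(),
                               df[cols["event"]].to_numpy())


def write_survival(ids, labels: SurvivalLabels, path) -> None:
    pd.DataFrame({"sample_id": ids, "time": labels.time,
                  "event": labels.event}).to_csv(path, sep="\t", index=False)


def read_image_stack(path) -> ImageStack:
    """Load an image stack from an ``.npz`` archive (keys: images, sample_ids)
    or from a directory of per-sample raster files (stem = sample id)."""
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no raster files found in {path}")
        arrays, ids = [], []
        for p in files:
            arr = np.asarray(iio.imread(p), dtype=float)
            if arr.ndim == 3:
                arr = arr.mean(axis=-1)
            peak = arr.max()
            arrays.append(arr / peak if peak > 1 else arr)
            ids.append(p.stem)
        return ImageStack(np.stack(arrays), ids)
    with np.load(path, allow_pickle=False) as npz:
        return ImageStack(npz["images"],
                          [str(s) for s in npz["sample_ids"]])


def write_image_stack(stack: ImageStack, path) -> None:
    np.savez_compressed(path, images=stack.values,
                        sample_ids=np.array(stack.sample_ids))


def write_dataset(dataset: RadiogenomicsDataset, out_dir,
                  ground_truth=None) -> None:
    """Write a dataset directory in the standard layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, out / "expression.tsv")
    write_clinical(dataset.clinical, out / "clinical.tsv")
    write_survival(dataset.sample_ids, dataset.labels, out / "survival.tsv")
    write_image_stack(dataset.images, out / "images.npz")
    if ground_truth is not None:
        np.savez_compressed(
            out / "ground_truth.npz",
            log_hazard=ground_truth.log_hazard,
            tumor_masks=ground_truth.tumor_masks,
            tumor_radius=ground_truth.tumor_radius,
            pathway_activity=ground_truth.pathway_activity,
            active_pathway_ids=np.array(ground_truth.active_pathway_ids),
        )


def read_dataset(in_dir) -> RadiogenomicsDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    from .preprocess import align_samples

    d = Path(in_dir)
    images = read_image_stack(d / "images.npz" if (d / "images.npz").exists()
                              else d / "images")
    expression = read_expression(d / "expression.tsv", allow_missing=False)
    clinical = read_clinical(d / "clinical.tsv")
    ids, labels = read_survival(d / "survival.tsv")
    return align_samples(images, expression, clinical, ids, labels)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
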