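"""Plain-text writers and readers for synthetic and user-provided data.

Counts travel as MatrixMarket MTX (genes x spots, as produced by common
spot-calling pipelines) with genes.tsv / barcodes.tsv sidecars; coordinates,
plaques and truth tables as TSV; images as multi-page TIFF with channel
names in the page description.
"""

from __future__ import annotations

import json
import os

import anndata as ad
import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .images import CHANNELS


def write_section(section: ad.AnnData, outdir: str) -> None:
    """Write one section: MTX counts (genes x spots), genes/barcodes, coords."""
    os.makedirs(outdir, exist_ok=True)
    counts = sparse.csr_matrix(np.asarray(section.X).T)
    spio.mmwrite(os.path.join(outdir, "matrix.mtx"), counts)
    pd.Series(section.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    pd.Series(section.obs_names).to_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", index=False, header=False
    )
    coords = section.obs.reset_index(names="spot_id")[
        ["section_id", "spot_id", "x_um", "y_um", "in_tissue"]
    ]
    coords.to_csv(os.path.join(outdir, "coords.tsv"), sep="\t", index=False)


def read_section(outdir: str) -> ad.AnnData:
    counts = spio.mmread(os.path.join(outdir, "matrix.mtx")).tocsr().T
    genes = pd.read_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", header=None
    )[0].astype(str)
    barcodes = pd.read_csv(
        os.path.join(outdir, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str)
    coords = pd.read_csv(os.path.join(outdir, "coords.tsv"), sep="\t").set_index(
        "spot_id"
    )
    section = ad.AnnData(
        X=np.asarray(counts.todense()),
        obs=coords.loc[barcodes],
        var=pd.DataFrame(index=genes),
    )
    return section


def write_plaques(plaques: pd.DataFrame, path: str) -> None:
    plaques[["section_id", "plaque_id", "x_um", "y_um"]].to_csv(
        path, sep="\t", index=False
    )


def read_plaques(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_reference(signatures, nuclei: ad.AnnData, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    spio.mmwrite(
        os.path.join(outdir, "nuclei.mtx"),
        sparse.csr_matrix(np.asarray(nuclei.X).T),
    )
    pd.Series(nuclei.var_names).to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False, header=False
    )
    nuclei.obs.reset_index(names="nucleus_id").to_csv(
        os.path.join(outdir, "labels.tsv"), sep="\t", index=False
    )
    signatures.means.to_csv(os.path.join(outdir, "true_signatures.tsv"), sep="\t")


def write_image(
    channels: dict[str, np.ndarray], path: str, pixel_size_um: float
) -> None:
    """Multi-page TIFF, one page per channel, channel names in metadata."""
    stack = np.stack([channels[c] for c in CHANNELS]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata=None,
        description=json.dumps(
            {"channels": list(CHANNELS), "pixel_size_um": pixel_size_um}
        ),
    )


def read_image(path: str) -> tuple[dict[str, np.ndarray], float]:
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    return channels, float(meta["pixel_size_um"])
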