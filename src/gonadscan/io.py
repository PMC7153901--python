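"""Plain-text and TIFF input/output.

Conventions: profiles and summaries are TSV with cd as the first
column; count matrices are TSV with gene_id first; axis geometry is
CSV so a hand-drawn polyline (e.g. exported from Fiji) can be used;
images are multi-page TIFF (pages = z * channels, channel-major) with
a JSON sidecar documenting channel order and metadata. Pixel
coordinates are 0-based (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .axisquant import AxisTrace
from .fociquant import FociSet
from .profilepipe import IntensityProfile, ProfileSummary
from .synth.images import GermlineImage

__all__ = [
    "write_profiles_tsv",
    "read_profiles_tsv",
    "write_summary_tsv",
    "write_axis_csv",
    "read_axis_csv",
    "write_foci_csv",
    "read_foci_csv",
    "write_counts_tsv",
    "read_counts_tsv",
    "read_gene_list",
    "write_gene_list",
    "save_image",
    "load_image",
]


def write_profiles_tsv(path, profiles: list[IntensityProfile]) -> None:
    """One cd column plus one value column per replicate."""
    data = {"cd": np.arange(1, profiles[0].max_cd + 1)}
    for p in profiles:
        data[p.replicate_id or p.genotype_label] = p.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path, genotype_label: str = "", state: str = "raw") -> list[IntensityProfile]:
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "cd":
        raise ValueError("first column of a profile TSV must be 'cd'")
    return [
        IntensityProfile(
            values=frame[col].to_numpy(float),
            genotype_label=genotype_label or col,
            replicate_id=col,
            state=state,
        )
        for col in frame.columns[1:]
    ]


def write_summary_tsv(path, summary: ProfileSummary) -> None:
    pd.DataFrame(
        {
            "cd": np.arange(1, summary.max_cd + 1),
            "mean": summary.mean,
            "sd": summary.sd,
            "n": summary.n,
        }
    ).to_csv(path, sep="\t", index=False)


def write_axis_csv(path, axis: AxisTrace) -> None:
    """Polyline points and marker arc positions in one CSV.

    Rows are tagged 'point' (y, x) or 'marker' (arc position in the
    y column).
    """
    rows = [("point", y, x) for y, x in axis.polyline]
    rows += [("marker", m, "") for m in axis.cd_markers]
    pd.DataFrame(rows, columns=["kind", "y", "x"]).to_csv(path, index=False)


def read_axis_csv(path, band_width_px: int = 100) -> AxisTrace:
    frame = pd.read_csv(path)
    points = frame[frame["kind"] == "point"][["y", "x"]].to_numpy(float)
    markers = frame[frame["kind"] == "marker"]["y"].to_numpy(float)
    return AxisTrace(
        polyline=points,
        cd_markers=markers,
        n_cd=markers.size - 1,
        band_width_px=band_width_px,
    )


def write_foci_csv(path, foci: FociSet) -> None:
    frame = foci.foci.copy()
    if "cd_bin" in frame.columns:
        frame["cd_bin"] = frame["cd_bin"].where(frame["cd_bin"] > 0, "excluded")
    frame.to_csv(path, index=False)


def read_foci_csv(path, threshold: float = float("nan"), min_voxels: int = 2) -> FociSet:
    frame = pd.read_csv(path)
    if "cd_bin" in frame.columns:
        frame = frame.drop(columns=["cd_bin"])
    return FociSet(foci=frame, threshold_used=threshold, min_voxels=min_voxels)


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_list(path, column: int = 0) -> list[str]:
    """Newline-delimited gene ids; tab-separated rows (e.g. a BED-style
    table with a gene column) are read by taking ``column`` verbatim."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        genes.append(fields[column if len(fields) > column else 0])
    return genes


def write_gene_list(path, genes) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def save_image(path, image: GermlineImage) -> None:
    """Channel-major multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    order = list(image.channels)
    stack = np.concatenate([image.channels[c] for c in order], axis=0)
    tifffile.imwrite(path, stack.astype(np.float32))
    sidecar = {
        "channel_order": order,
        "z_slices": int(next(iter(image.channels.values())).shape[0]),
        "pixel_size_um": image.pixel_size_um,
        "genotype_label": image.genotype_label,
        "tagged": image.tagged,
        "metadata": {k: v for k, v in image.metadata.items() if not isinstance(v, np.ndarray)},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_image(path) -> GermlineImage:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(path).astype(float)
    nz = sidecar["z_slices"]
    channels = {
        name: stack[i * nz : (i + 1) * nz]
        for i, name in enumerate(sidecar["channel_order"])
    }
    return GermlineImage(
        channels=channels,
        pixel_size_um=sidecar["pixel_size_um"],
        genotype_label=sidecar["genotype_label"],
        tagged=sidecar["tagged"],
        metadata=sidecar.get("metadata", {}),
    )
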