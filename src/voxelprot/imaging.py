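"""Voxel-grid protein images, reproducibility (CV) summaries and a static gallery.

One LCM voxel = one LC-MS run = one image pixel. Grids use (row, col)
coordinates, 0-based, row 0 at the top (image convention); unoccupied or
missing cells carry NaN and render grey. Coefficients of variation are
always computed on linear-scale intensities (sd/mean of 2**log2 values) —
a CV on log values is not a CV.
"""

from __future__ import annotations

import html
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .matrices import ProteinMatrix, SampleMetadata


@dataclass
class VoxelImage:
    analyte_id: str
    grid: np.ndarray            # (H, W) float, NaN = missing/unoccupied
    voxel_size_um: float
    study_id: str
    sample_at: dict[tuple[int, int], str]   # occupied cell -> sample id

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def build_voxel_image(
    values: pd.Series, meta: SampleMetadata, analyte_id: str
) -> VoxelImage:
    """Place per-sample values onto the LCM voxel grid.

    ``values`` is indexed by sample id; every sample must belong to the same
    imaging study and claim a unique (row, col).
    """
    t = meta.table.loc[list(values.index)]
    studies = t["study_id"].unique()
    if len(studies) != 1:
        raise ValueError(f"samples span multiple studies: {list(studies)}")
    sizes = t["voxel_size_um"].unique()
    coords = list(zip(t["voxel_row"], t["voxel_col"]))
    if len(set(coords)) != len(coords):
        seen, dup = set(), None
        for c in coords:
            if c in seen:
                dup = c
                break
            seen.add(c)
        raise ValueError(f"duplicate voxel coordinate: {dup}")
    h = int(t["voxel_row"].max()) + 1
    w = int(t["voxel_col"].max()) + 1
    grid = np.full((h, w), np.nan)
    sample_at = {}
    for sample_id, row in t.iterrows():
        r, c = int(row["voxel_row"]), int(row["voxel_col"])
        grid[r, c] = values[sample_id]
        sample_at[(r, c)] = sample_id
    return VoxelImage(
        analyte_id=analyte_id,
        grid=grid,
        voxel_size_um=float(sizes[0]),
        study_id=str(studies[0]),
        sample_at=sample_at,
    )


def _scale_grid(grid: np.ndarray, scaling: str, p_lo: float, p_hi: float) -> np.ndarray:
    present = grid[~np.isnan(grid)]
    if present.size == 0:
        raise ValueError("all-missing image cannot be rendered")
    if scaling == "minmax":
        lo, hi = present.min(), present.max()
    elif scaling == "percentile":
        lo, hi = np.percentile(present, [p_lo, p_hi])
    else:
        raise ValueError(f"unknown scaling: {scaling!r}")
    span = hi - lo
    if span == 0:
        return np.where(np.isnan(grid), np.nan, 1.0)
    return np.clip((grid - lo) / span, 0.0, 1.0)


def render_protein_image(
    img: VoxelImage,
    out_path: str | Path,
    scaling: str = "minmax",
    p_lo: float = 5.0,
    p_hi: float = 95.0,
    colormap: str = "viridis",
    pixel_size: int = 32,
) -> np.ndarray:
    """Render the voxel grid to a PNG and a CSV sidecar; returns the scaled grid.

    Present values map through ``scaling`` onto [0, 1] then a monotone
    colormap; missing cells render grey. The sidecar (same stem, ``.csv``)
    stores the unscaled grid and round-trips exactly; its header records the
    analyte, study, voxel size (from which a scale bar derives) and shape.
    """
    out_path = Path(out_path)
    scaled = _scale_grid(img.grid, scaling, p_lo, p_hi)
    cmap = colormaps[colormap]
    rgba = cmap(np.nan_to_num(scaled, nan=0.0))
    rgba[np.isnan(scaled)] = (0.5, 0.5, 0.5, 1.0)  # grey sentinel
    from PIL import Image

    im = Image.fromarray((rgba[:, :, :3] * 255).astype(np.uint8), mode="RGB")
    h, w = img.shape
    im = im.resize((w * pixel_size, h * pixel_size), Image.NEAREST)
    im.save(out_path)
    write_grid_csv(img, out_path.with_suffix(".csv"))
    return scaled


def write_grid_csv(img: VoxelImage, path: str | Path) -> None:
    h, w = img.shape
    with open(path, "w") as fh:
        fh.write(f"# analyte={img.analyte_id}\n")
        fh.write(f"# study={img.study_id}\n")
        fh.write(f"# voxel_size_um={img.voxel_size_um:g}\n")
        fh.write(f"# H={h} W={w} origin=top-left rows=top-down\n")
        for r in range(h):
            fh.write(",".join("" if np.isnan(v) else f"{v:.17g}" for v in img.grid[r]) + "\n")


def read_grid_csv(path: str | Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            rows.append(
                [np.nan if cell == "" else float(cell) for cell in line.rstrip("\n").split(",")]
            )
    return np.array(rows, dtype=float)


def cv_summary(
    prot: ProteinMatrix,
    replicate_samples: list[str] | None = None,
    bin_width: float = 0.05,
) -> dict:
    """Per-protein linear-scale CVs across replicate runs.

    CV = sample sd (ddof=1) / mean of the 2**log2 intensities; proteins
    observed in fewer than 2 replicates are excluded. Returns the per-protein
    table, the global median CV and histogram bin counts of ``bin_width``.
    """
    samples = replicate_samples or prot.sample_ids
    if len(samples) < 2:
        raise ValueError("need at least 2 replicate samples")
    linear = np.power(2.0, prot.abundance[samples])
    n_used = linear.notna().sum(axis=1)
    import warnings

    with warnings.catch_warnings():
        # proteins absent from every replicate yield empty slices; they are
        # excluded below anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = linear.mean(axis=1)
        sd = linear.std(axis=1, ddof=1)
    cv = (sd / mean)[n_used >= 2]
    table = pd.DataFrame({"cv": cv, "n_used": n_used[n_used >= 2]})
    table.index.name = "protein_id"
    if len(cv):
        edges = np.arange(0.0, float(cv.max()) + 2 * bin_width, bin_width)
        hist, _ = np.histogram(cv, bins=edges)
    else:
        edges, hist = np.array([0.0, bin_width]), np.array([0])
    return {
        "table": table,
        "median_cv": float(cv.median()) if len(cv) else np.nan,
        "hist_counts": hist,
        "hist_edges": edges,
    }


_INDEX_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Protein image gallery</title>
<style>
body {{ font-family: sans-serif; margin: 1em; }}
.panel {{ display: inline-block; margin: 8px; text-align: center; vertical-align: top; }}
.panel img {{ image-rendering: pixelated; border: 1px solid #888; }}
.meta {{ font-size: 11px; color: #444; }}
</style>
<script>
function filterPanels() {{
  var q = document.getElementById('q').value.toLowerCase();
  var panels = document.getElementsByClassName('panel');
  for (var i = 0; i < panels.length; i++) {{
    var key = panels[i].getAttribute('data-key');
    panels[i].style.display = key.indexOf(q) >= 0 ? 'inline-block' : 'none';
  }}
}}
</script></head>
<body>
<h1>Protein image gallery</h1>
<input id="q" type="text" placeholder="filter by protein / gene" onkeyup="filterPanels()" size="40">
<div>
{panels}
</div>
</body></html>
"""

_PANEL_TEMPLATE = """<div class="panel" data-key="{key}">
<a href="{png}"><img src="{png}" alt="{analyte}" width="{w}"></a><br>
<b>{analyte}</b> {gene}<br>
<span class="meta">{meta}</span>
</div>"""


def export_gallery(
    images: dict[str, VoxelImage],
    out_dir: str | Path,
    metadata: dict[str, str] | None = None,
    gene_symbols: dict[str, str] | None = None,
    scaling: str = "minmax",
    colormap: str = "viridis",
) -> dict:
    """Write one PNG + one CSV per analyte plus a self-contained index page.

    File names are the analyte accession (sanitised); the index carries a
    client-side text filter on analyte id / gene symbol and is byte-identical
    across runs on identical input (deterministic ordering).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels = []
    seen_names: set[str] = set()
    for analyte in sorted(images):
        img = images[analyte]
        stem = "".join(c if (c.isalnum() or c in "._-") else "_" for c in analyte)
        if stem in seen_names:
            raise ValueError(f"gallery file-name collision: {stem}")
        seen_names.add(stem)
        png = f"{stem}.png"
        render_protein_image(img, out_dir / png, scaling=scaling, colormap=colormap)
        gene = (gene_symbols or {}).get(analyte, "")
        meta = (metadata or {}).get(analyte, "")
        key = html.escape(f"{analyte} {gene}".lower())
        panels.append(
            _PANEL_TEMPLATE.format(
                key=key,
                png=html.escape(png),
                analyte=html.escape(analyte),
                gene=html.escape(gene),
                meta=html.escape(meta),
                w=img.shape[1] * 32,
            )
        )
    index = _INDEX_TEMPLATE.format(panels="\n".join(panels))
    (out_dir / "index.html").write_text(index)
    return {"n_panels": len(panels), "out_dir": str(out_dir)}
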