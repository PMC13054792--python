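"""Pairwise similarity heatmaps: which regions of two images drive their match.

For final-layer feature maps A (spatial positions u, channel vectors a_u)
and B (positions v, vectors b_v), the raw contribution of position u in A
to the pair's similarity is

    raw_A(u) = Σ_v ⟨a_u, b_v⟩ = ⟨a_u, Σ_v b_v⟩,

and symmetrically for B.  This is the pairwise dot-product decomposition of
the average-pooled descriptor similarity: summing raw_A over all positions
gives exactly ``W·H·W'·H' × ⟨avg-pool(A), avg-pool(B)⟩`` — an identity that
makes the attribution testable.  Negative contributions are clipped at zero
and each map is max-normalized to [0, 1] for display (red = high mutual
similarity).  The decomposition uses average-pooling algebra even though
retrieval embeddings are GeM-pooled; the maps are qualitative attributions,
not exact gradients of the retrieval distance.

Display upsampling to input resolution is bilinear and presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["HeatmapPair", "similarity_heatmap", "upsample_heatmap", "save_heatmap_overlay", "export_heatmap_text"]


@dataclass
class HeatmapPair:
    """Normalized [0,1] attribution maps plus the raw contribution grids."""

    map_query: np.ndarray  # (H, W) in [0, 1]
    map_match: np.ndarray  # (H', W') in [0, 1]
    raw_query: np.ndarray  # pre-clipping contributions
    raw_match: np.ndarray


def _as_khw(fmap: np.ndarray) -> np.ndarray:
    f = np.asarray(fmap, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError(f"feature map must be 3-D (K, H, W), got shape {f.shape}")
    return f


def similarity_heatmap(fmap_a: np.ndarray, fmap_b: np.ndarray) -> HeatmapPair:
    """Decompose the similarity of two (K, H, W) feature maps into spatial maps.

    All-zero feature maps yield all-zero maps (normalization is skipped when
    the maximum is zero).
    """
    a = _as_khw(fmap_a)
    b = _as_khw(fmap_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"channel count mismatch: {a.shape[0]} vs {b.shape[0]}")
    sum_a = a.sum(axis=(1, 2))  # (K,)
    sum_b = b.sum(axis=(1, 2))
    raw_a = np.tensordot(sum_b, a, axes=(0, 0))  # (H, W)
    raw_b = np.tensordot(sum_a, b, axes=(0, 0))

    def _norm(raw: np.ndarray) -> np.ndarray:
        clipped = np.clip(raw, 0.0, None)
        peak = clipped.max()
        return clipped / peak if peak > 0 else clipped

    return HeatmapPair(map_query=_norm(raw_a), map_match=_norm(raw_b), raw_query=raw_a, raw_match=raw_b)


def upsample_heatmap(heat: np.ndarray, size: int) -> np.ndarray:
    """Bilinear display upsampling of a heatmap to ``size``×``size``."""
    im = Image.fromarray(heat.astype(np.float32), mode="F")
    return np.asarray(im.resize((size, size), resample=Image.BILINEAR), dtype=np.float32)


def save_heatmap_overlay(image: np.ndarray, heat: np.ndarray, path: str | Path, alpha: float = 0.45) -> Path:
    """Save the heatmap as a jet-colored overlay on the grayscale image (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    img = np.asarray(image, dtype=np.float64)
    rng = img.max() - img.min()
    img = (img - img.min()) / rng if rng > 0 else np.zeros_like(img)
    heat_up = upsample_heatmap(heat, img.shape[0]) if heat.shape != img.shape else heat
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(img, cmap="gray", interpolation="bilinear")
    ax.imshow(heat_up, cmap="jet", alpha=alpha, interpolation="bilinear", vmin=0.0, vmax=1.0)
    ax.axis("off")
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
    return path


def export_heatmap_text(pair: HeatmapPair, path: str | Path) -> Path:
    """Write both normalized grids as a delimited text file."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, grid in (("map_query", pair.map_query), ("map_match", pair.map_match)):
            fh.write(f"# {name} shape={grid.shape[0]}x{grid.shape[1]}\n")
            np.savetxt(fh, grid, fmt="%.6f", delimiter="\t")
    return path
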