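"""Genome-wide eQTL map: association scatter, per-SNP counts and hotspot scores.

Three stacked panels over a shared genomic x-axis of cumulative base-pair
offsets (chromosomes ordered 1-22): the bottom panel scatters each
significant SNP-probe pair at (SNP position, probe position) with darkness
increasing in -log10 p; the middle panel shows per-SNP significant-probe
counts as circles with radius growing with the count; the top panel tracks
the hotspot enrichment score (-log10 of the Bonferroni-corrected binomial
p) per SNP.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _chrom_key(c: str):
    try:
        return (0, int(c))
    except (TypeError, ValueError):
        return (1, str(c))


def genome_offsets(*annotations: pd.DataFrame) -> dict[str, float]:
    """Cumulative bp offset per chromosome across the union of annotations."""
    sizes: dict[str, float] = {}
    for ann in annotations:
        for chrom, pos in zip(ann["chrom"], ann["pos"]):
            c = str(chrom)
            sizes[c] = max(sizes.get(c, 0.0), float(pos))
    offsets: dict[str, float] = {}
    total = 0.0
    for c in sorted(sizes, key=_chrom_key):
        offsets[c] = total
        total += sizes[c]
    return offsets


def _genome_x(ids, ann: pd.DataFrame, offsets: dict[str, float]) -> np.ndarray:
    sub = ann.reindex(ids)
    return np.asarray(
        [offsets.get(str(c), np.nan) + float(p)
         for c, p in zip(sub["chrom"], sub["pos"])]
    )


def plot_eqtl_map(records, hotspots, snp_ann: pd.DataFrame, probe_ann: pd.DataFrame,
                  out_path: str | Path) -> Path:
    """Render the three-panel eQTL map to ``out_path`` (raster or vector by suffix)."""
    records = list(records)
    offsets = genome_offsets(snp_ann, probe_ann)
    fig, axes = plt.subplots(
        3, 1, figsize=(10, 9), sharex=True,
        gridspec_kw={"height_ratios": [1, 1, 3]},
    )
    ax_score, ax_count, ax_scatter = axes

    if not records:
        log.warning("no significant eQTL records; writing an empty-panel figure")
    else:
        sx = _genome_x([r.snp_id for r in records], snp_ann, offsets)
        py = _genome_x([r.probe_id for r in records], probe_ann, offsets)
        neglog = -np.log10(np.maximum([r.p for r in records], 1e-300))
        ax_scatter.scatter(sx, py, c=neglog, cmap="Greys", vmin=0.0, s=6,
                           edgecolors="none")
        counts: dict[str, int] = {}
        for r in records:
            counts[r.snp_id] = counts.get(r.snp_id, 0) + 1
        cx = _genome_x(list(counts), snp_ann, offsets)
        cn = np.asarray(list(counts.values()), dtype=float)
        ax_count.scatter(cx, np.zeros_like(cx), s=12 * cn, facecolors="none",
                         edgecolors="black", linewidths=0.7)
    if hotspots:
        hx = _genome_x([h.snp_id for h in hotspots], snp_ann, offsets)
        ax_score.stem([float(v) for v in hx],
                      [h.enrichment_score for h in hotspots], basefmt=" ")

    boundaries = sorted(offsets.values())
    for ax in axes:
        for b in boundaries[1:]:
            ax.axvline(b, color="0.85", lw=0.5, zorder=0)
    ax_score.set_ylabel("-log10 corrected p")
    ax_count.set_ylabel("probe count")
    ax_count.set_yticks([])
    ax_scatter.set_ylabel("probe genomic position (bp)")
    ax_scatter.set_xlabel("SNP genomic position (bp)")
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
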