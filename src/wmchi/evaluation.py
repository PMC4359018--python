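"""Artifact metrics: difference-from-truth maps, WM heterogeneity, ROI stats.

The study's evaluation surface is deliberately simple: reconstructed maps are
compared against the known ground truth voxelwise (DFT maps), white-matter
heterogeneity is summarised by the standard deviation over the WM mask, and
named regions are summarised by mean +/- SD.  Standard deviations are
population (N) SDs throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .volumes import ScalarVolume

__all__ = ["RoiReport", "dft_map", "wm_sd", "roi_stats"]


@dataclass(frozen=True)
class RoiReport:
    name: str
    mean: float
    sd: float
    n_voxels: int


def dft_map(recon: ScalarVolume, truth: ScalarVolume) -> ScalarVolume:
    """Difference-from-truth map: reconstruction minus ground truth."""
    if recon.data.shape != truth.data.shape:
        raise ValueError("reconstruction and truth must share a grid")
    if recon.units != truth.units:
        raise ValueError(
            f"units mismatch: {recon.units} vs {truth.units}"
        )
    return recon.with_data(recon.data - truth.data)


def wm_sd(vol: ScalarVolume, wm_mask: np.ndarray) -> float:
    """Population SD of the map over the white-matter mask."""
    wm_mask = np.asarray(wm_mask, dtype=bool)
    if not wm_mask.any():
        raise ValueError("white-matter mask is empty")
    return float(vol.data[wm_mask].std())


def roi_stats(vol: ScalarVolume, masks: dict[str, np.ndarray]) -> list[RoiReport]:
    """Mean +/- population SD per named region; empty regions are skipped."""
    reports = []
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            import warnings

            warnings.warn(f"ROI {name!r} is empty; skipped", RuntimeWarning)
            continue
        vals = vol.data[mask]
        reports.append(
            RoiReport(name, float(vals.mean()), float(vals.std()), int(mask.sum()))
        )
    return reports


def roi_table(reports: list[RoiReport]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in reports]).set_index("name")
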