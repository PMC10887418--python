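"""Force-volume stiffness mapping, region summaries and map rendering.

A force volume (one curve per pixel) becomes a per-pixel Young's-modulus
map.  Pixels whose curve cannot be fitted are marked invalid — never
dropped silently — and all region statistics run over valid pixels only.
The rendered projection maps the lowest stiffness in the image to blue and
the highest to red, with invalid pixels gray, mirroring the conventional
elasticity-projection display.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .contact import ElasticFit, IndentationModel
from .curves import ForceVolume, SampleClassSettings

__all__ = [
    "StiffnessMap",
    "RegionSummary",
    "ForceVolumeModel",
    "StiffnessMapResults",
    "fit_volume",
    "summarize_region",
    "render_map",
]


@dataclass
class StiffnessMap:
    """Grid of per-pixel moduli with a validity mask."""

    moduli_pa: np.ndarray
    valid: np.ndarray
    pixel_pitch_m: float

    def __post_init__(self) -> None:
        self.moduli_pa = np.asarray(self.moduli_pa, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.moduli_pa.shape != self.valid.shape:
            raise ValueError("moduli and valid grids must be congruent")
        vals = self.moduli_pa[self.valid]
        if vals.size and not (np.all(np.isfinite(vals)) and np.all(vals > 0)):
            raise ValueError("valid pixels must hold positive finite moduli")

    @property
    def shape(self) -> tuple[int, int]:
        return self.moduli_pa.shape

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class RegionSummary:
    """Stiffness statistics over the valid pixels of one region."""

    region_label: str
    n_valid: int
    median_pa: float
    mean_pa: float
    sd_pa: float

    @property
    def median_kpa(self) -> float:
        return self.median_pa / 1e3


def summarize_region(
    stiffness_map: StiffnessMap,
    mask: Optional[np.ndarray] = None,
    label: str = "region",
) -> RegionSummary:
    """Median/mean/SD modulus over ``valid & mask`` pixels.

    The even-count median is the mean of the two central values (numpy
    convention).  An empty effective region is an error.
    """
    if mask is None:
        mask = np.ones(stiffness_map.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stiffness_map.shape:
        raise ValueError("mask must be congruent with the stiffness map")
    eff = stiffness_map.valid & mask
    if not eff.any():
        raise ValueError(f"region '{label}' contains no valid pixels")
    vals = stiffness_map.moduli_pa[eff]
    return RegionSummary(
        region_label=label,
        n_valid=int(eff.sum()),
        median_pa=float(np.median(vals)),
        mean_pa=float(np.mean(vals)),
        sd_pa=float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
    )


def fit_volume(
    volume: ForceVolume, settings: SampleClassSettings
) -> StiffnessMap:
    """Fit every pixel of a force volume; failed fits become invalid pixels."""
    return ForceVolumeModel(volume, settings).fit().stiffness_map


class ForceVolumeModel:
    """Per-pixel contact-model fitting over a force volume."""

    def __init__(self, volume: ForceVolume, settings: SampleClassSettings) -> None:
        self.volume = volume
        self.settings = settings

    def fit(self) -> "StiffnessMapResults":
        rows, cols = self.volume.rows, self.volume.cols
        moduli = np.full((rows, cols), np.nan)
        valid = np.zeros((rows, cols), dtype=bool)
        fits: list[list[ElasticFit]] = []
        for r in range(rows):
            fit_row = []
            for c in range(cols):
                try:
                    res = IndentationModel(
                        self.volume.grid[r][c], self.settings
                    ).fit()
                    fit = res.elastic_fit
                except ValueError as exc:
                    fit = ElasticFit(
                        modulus_pa=float("nan"),
                        contact_index=-1,
                        rmse_n=float("nan"),
                        delta_max_m=0.0,
                        n_points_fit=0,
                        flags={"poor_fit"},
                        note=str(exc),
                    )
                fit_row.append(fit)
                if fit.valid:
                    moduli[r, c] = fit.modulus_pa
                    valid[r, c] = True
            fits.append(fit_row)
        smap = StiffnessMap(
            moduli_pa=moduli, valid=valid, pixel_pitch_m=self.volume.pixel_pitch_m
        )
        return StiffnessMapResults(self, smap, fits)


class StiffnessMapResults:
    """Fitted stiffness map plus per-pixel fit diagnostics."""

    def __init__(
        self,
        model: ForceVolumeModel,
        stiffness_map: StiffnessMap,
        fits: list[list[ElasticFit]],
    ) -> None:
        self.model = model
        self.stiffness_map = stiffness_map
        self.fits = fits

    def summarize_region(
        self, mask: Optional[np.ndarray] = None, label: str = "region"
    ) -> RegionSummary:
        return summarize_region(self.stiffness_map, mask, label)

    def render(self, out_path, **kwargs) -> Path:
        return render_map(self.stiffness_map, out_path, **kwargs)

    def summary(self) -> str:
        smap = self.stiffness_map
        rows, cols = smap.shape
        lines = [
            "Stiffness map summary",
            "=" * 40,
            f"grid:          {rows} x {cols} ({rows * cols} curves)",
            f"valid pixels:  {smap.n_valid} / {rows * cols}",
            f"pixel pitch:   {smap.pixel_pitch_m * 1e6:.3g} um",
        ]
        if smap.n_valid:
            s = summarize_region(smap, label="full map")
            lines += [
                f"median E:      {s.median_kpa:.4g} kPa",
                f"mean E:        {s.mean_pa / 1e3:.4g} kPa",
                f"SD E:          {s.sd_pa / 1e3:.4g} kPa",
            ]
        return "\n".join(lines)


def _to_rgb(
    smap: StiffnessMap,
    color_low: tuple = (0, 0, 255),
    color_high: tuple = (255, 0, 0),
    vmin: Optional[float] = None,
    vmax: Optional[float] = None,
    invalid_gray: int = 128,
) -> np.ndarray:
    vals = smap.moduli_pa
    if vmin is None:
        vmin = float(np.min(vals[smap.valid]))
    if vmax is None:
        vmax = float(np.max(vals[smap.valid]))
    span = vmax - vmin
    t = np.zeros_like(vals) if span == 0 else np.clip((vals - vmin) / span, 0, 1)
    low = np.asarray(color_low, dtype=float)
    high = np.asarray(color_high, dtype=float)
    rgb = low[None, None, :] + t[..., None] * (high - low)[None, None, :]
    rgb[~smap.valid] = invalid_gray
    return rgb.astype(np.uint8)


def render_map(
    smap: StiffnessMap,
    out_path: Union[str, Path],
    color_low: tuple = (0, 0, 255),
    color_high: tuple = (255, 0, 0),
    vmin: Optional[float] = None,
    vmax: Optional[float] = None,
    upscale: int = 16,
    scale_bar: bool = True,
) -> Path:
    """Write the blue-to-red stiffness projection as a PNG.

    The color scale runs linearly from the map minimum (blue) to the map
    maximum (red) unless a fixed range (vmin, vmax) is given for
    cross-image comparability; invalid pixels are gray.  Each map pixel is
    drawn ``upscale`` image pixels wide and a white scale bar sized from the
    pixel pitch is burned into the bottom-left corner.
    """
    from PIL import Image

    if not smap.valid.any():
        raise ValueError("cannot render a map with no valid pixels")
    rgb = _to_rgb(smap, color_low, color_high, vmin, vmax)
    big = np.repeat(np.repeat(rgb, upscale, axis=0), upscale, axis=1)
    if scale_bar:
        # bar spanning a quarter of the scan width, rounded to whole pixels
        bar_map_px = max(1, smap.shape[1] // 4)
        bar_len = bar_map_px * upscale
        h = big.shape[0]
        thickness = max(2, upscale // 4)
        big[h - 2 * thickness : h - thickness, upscale // 2 : upscale // 2 + bar_len] = 255
    img = Image.fromarray(big, mode="RGB")
    out_path = Path(out_path)
    meta = None
    try:
        from PIL.PngImagePlugin import PngInfo

        meta = PngInfo()
        meta.add_text("pixel_pitch_m", repr(smap.pixel_pitch_m))
        if scale_bar:
            meta.add_text(
                "scale_bar_m", repr(bar_map_px * smap.pixel_pitch_m)
            )
    except ImportError:  # pragma: no cover
        pass
    img.save(out_path, pnginfo=meta)
    return out_path
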