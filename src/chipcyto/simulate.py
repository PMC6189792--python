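"""Synthetic fluorescence microscope for DNA-content cytometry benchmarks.

Generates fields of spread, DAPI-stained nuclei with known ground truth.
Per-cell DNA content is drawn from a cell-cycle mixture (G1 at 2N, S uniform
on 2N-4N, G2/M at 4N, plus sub-G1 debris and unresolved doublets), rendered
as truncated Gaussian disks whose integrated signal is

    gain * exposure_ms * sat(content),   sat(c) = c * K / (c + K),

so that signal is linear in DNA content for large half-saturation constant K
and compresses toward K as staining saturates (the over-concentrated-dye
failure mode).  Detector model: Poisson shot noise on signal counts, Gaussian
read noise/offset as background, hard clipping at ``detector_max``.

All randomness flows through explicit integer seeds; identical inputs give
bit-identical fields and ground-truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import PlacementError

__all__ = [
    "PHASES",
    "CellCycleMixture",
    "OpticsConfig",
    "FieldImage",
    "GroundTruthTable",
    "sample_dna_contents",
    "saturate",
    "render_field",
    "simulate_dataset",
    "write_field",
    "read_field",
    "write_ground_truth",
]

#: Phase labels in sampling order.  "debris" is sub-G1 fragments (< 2N),
#: "doublet" an unresolved pair of cells quantified as one object (> 4N).
PHASES = ("G1", "S", "G2M", "debris", "doublet")

_MIN_SEPARATION_PX = 4.0  # gap between non-clumped nucleus rims
_CLUMP_DISTANCE_RANGE = (0.7, 0.9)  # centre distance as fraction of r1+r2


@dataclass(frozen=True)
class CellCycleMixture:
    """Ground-truth composition of a cell population.

    Fractions are unitless and must sum to 1.  DNA content is measured in
    "N units": G1 cells carry 2, G2/M cells 4, S cells between 2 and 4.
    ``cv`` is the coefficient of variation of measured content around its
    phase value (staining/measurement spread).
    """

    f_g1: float
    f_s: float
    f_g2m: float
    f_debris: float = 0.0
    f_doublet: float = 0.0
    cv: float = 0.06

    def __post_init__(self) -> None:
        fracs = self.fractions
        if np.any(fracs < 0):
            raise ValueError(f"mixture fractions must be >= 0, got {fracs}")
        if not math.isclose(float(fracs.sum()), 1.0, abs_tol=1e-8):
            raise ValueError(
                f"mixture fractions must sum to 1, got {float(fracs.sum()):.6g}"
            )
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")

    @property
    def fractions(self) -> np.ndarray:
        return np.array(
            [self.f_g1, self.f_s, self.f_g2m, self.f_debris, self.f_doublet],
            dtype=float,
        )


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition/rendering parameters of the synthetic microscope.

    ``gain`` is detector counts per N-unit of DNA per millisecond of
    exposure.  ``saturation_k`` (N units) is the half-saturation constant of
    the staining curve; ``inf`` means perfectly linear staining.  Dye
    concentration maps monotonically onto it (more dye = lower K).
    Magnification maps onto ``nucleus_radius_px`` (up) together with
    ``cells_per_field`` (down).
    """

    exposure_ms: float = 5.0
    gain: float = 2000.0
    detector_max: int = 65535
    background_mean: float = 100.0
    background_sd: float = 3.0
    saturation_k: float = math.inf
    nucleus_radius_px: tuple[float, float] = (5.0, 0.5)  # mean, sd
    field_shape: tuple[int, int] = (900, 900)
    cells_per_field: int = 150
    clump_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.exposure_ms <= 0:
            raise ValueError("gain and exposure_ms must be > 0")
        if not (self.detector_max > self.background_mean >= 0):
            raise ValueError("require detector_max > background_mean >= 0")
        if self.background_sd < 0:
            raise ValueError("background_sd must be >= 0")
        if self.nucleus_radius_px[0] < 2:
            raise ValueError("mean nucleus radius must be >= 2 px")
        if not 0 <= self.clump_prob <= 1:
            raise ValueError("clump_prob must be in [0, 1]")
        if self.saturation_k <= 0:
            raise ValueError("saturation_k must be > 0 (inf = linear)")


@dataclass(frozen=True)
class FieldImage:
    """One acquired (or rendered) fluorescence field plus metadata."""

    pixels: np.ndarray  # 2-D, non-negative integers
    exposure_ms: float
    detector_max: int
    magnification: str = ""
    dye: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"field must be a 2-D grid >= 16x16, got {px.shape}")
        if px.min() < 0 or px.max() > self.detector_max:
            raise ValueError("pixel values must lie in [0, detector_max]")


@dataclass(frozen=True)
class GroundTruthTable:
    """Per-nucleus truth for a rendered field.

    ``table`` has one row per placed nucleus (columns: nucleus_id, phase,
    content, centroid_row, centroid_col, radius_px, clumped); ``labels`` is
    the matching label image (0 = background, i = nucleus ``nucleus_id`` i).
    """

    table: pd.DataFrame
    labels: np.ndarray


def _cycling_contents(
    phase_idx: np.ndarray, rng: np.random.Generator, cv: float
) -> np.ndarray:
    """Contents for cycling cells (phase index 0=G1, 1=S, 2=G2M)."""
    out = np.empty(phase_idx.size, dtype=float)
    g1 = phase_idx == 0
    s = phase_idx == 1
    g2 = phase_idx == 2
    out[g1] = 2.0 * (1.0 + rng.normal(0.0, cv, int(g1.sum())))
    out[s] = rng.uniform(2.0, 4.0, int(s.sum())) * (
        1.0 + rng.normal(0.0, cv, int(s.sum()))
    )
    out[g2] = 4.0 * (1.0 + rng.normal(0.0, cv, int(g2.sum())))
    return out


def sample_dna_contents(
    mixture: CellCycleMixture, n: int, seed: int
) -> pd.DataFrame:
    """Draw ``n`` (phase, content) pairs i.i.d. from ``mixture``.

    Doublet content is the sum of two independent draws from the cycling
    (G1/S/G2M) part of the mixture.  Returns a DataFrame with columns
    ``phase`` (str) and ``content`` (N units); same seed, same output.
    """
    if n < 1:
        raise ValueError(f"need at least one cell, got n={n}")
    rng = np.random.default_rng(seed)
    fracs = mixture.fractions
    idx = rng.choice(len(PHASES), size=n, p=fracs)
    content = np.empty(n, dtype=float)

    cyc = idx <= 2
    content[cyc] = _cycling_contents(idx[cyc], rng, mixture.cv)
    deb = idx == 3
    content[deb] = rng.uniform(0.5, 1.8, int(deb.sum()))
    dbl = idx == 4
    n_dbl = int(dbl.sum())
    if n_dbl:
        cyc_w = fracs[:3]
        if cyc_w.sum() <= 0:
            raise ValueError(
                "doublets require a nonzero cycling (G1/S/G2M) component"
            )
        pair_idx = rng.choice(3, size=2 * n_dbl, p=cyc_w / cyc_w.sum())
        pair = _cycling_contents(pair_idx, rng, mixture.cv)
        content[dbl] = pair[:n_dbl] + pair[n_dbl:]

    content = np.maximum(content, 1e-6)
    return pd.DataFrame(
        {"phase": np.array(PHASES, dtype=object)[idx], "content": content}
    )


def saturate(content: np.ndarray | float, saturation_k: float) -> np.ndarray | float:
    """Staining response: content for K=inf, Michaelis-Menten compression else."""
    if math.isinf(saturation_k):
        return content
    return content * saturation_k / (content + saturation_k)


def _as_content_table(contents) -> pd.DataFrame:
    if isinstance(contents, pd.DataFrame):
        df = contents[["phase", "content"]].reset_index(drop=True)
    else:
        df = pd.DataFrame(list(contents), columns=["phase", "content"])
    if len(df) == 0:
        raise ValueError("contents must be non-empty")
    if (df["content"] <= 0).any():
        raise ValueError("DNA contents must be > 0")
    return df


def _place_nuclei(
    radii: np.ndarray,
    shape: tuple[int, int],
    clump_prob: float,
    rng: np.random.Generator,
    max_attempts: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Place nucleus centres; returns (centres[n,2], clumped[n] bool).

    Non-clumped nuclei keep a rim gap >= _MIN_SEPARATION_PX; a clumped
    nucleus is dropped touching a randomly chosen earlier one.
    """
    n = radii.size
    rows, cols = shape
    centres = np.empty((n, 2), dtype=float)
    clumped = np.zeros(n, dtype=bool)
    for i in range(n):
        r = radii[i]
        margin = r + _MIN_SEPARATION_PX
        if rows - 2 * margin <= 0 or cols - 2 * margin <= 0:
            raise PlacementError(
                f"field {shape} too small for nucleus radius {r:.1f}"
            )
        want_clump = i > 0 and rng.random() < clump_prob
        for _ in range(max_attempts):
            if want_clump:
                j = int(rng.integers(i))
                u = rng.uniform(*_CLUMP_DISTANCE_RANGE)
                theta = rng.uniform(0.0, 2.0 * math.pi)
                d = u * (r + radii[j])
                c = centres[j] + d * np.array([math.cos(theta), math.sin(theta)])
                if not (
                    margin <= c[0] <= rows - margin
                    and margin <= c[1] <= cols - margin
                ):
                    continue
                others = [k for k in range(i) if k != j]
            else:
                c = rng.uniform([margin, margin], [rows - margin, cols - margin])
                others = range(i)
            ok = True
            for k in others:
                sep = r + radii[k] + _MIN_SEPARATION_PX
                if np.hypot(*(c - centres[k])) < sep:
                    ok = False
                    break
            if ok:
                centres[i] = c
                if want_clump:
                    clumped[i] = True
                    clumped[j] = True
                break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{n} in field {shape}; "
                "reduce cells_per_field or enlarge the field"
            )
    return centres, clumped


def render_field(
    contents, optics: OpticsConfig
) -> tuple[FieldImage, GroundTruthTable]:
    """Render one fluorescence field from per-cell DNA contents.

    Each nucleus is a 2-D Gaussian disk (sigma = radius/3, truncated at the
    radius) whose pre-noise, pre-clip integrated signal equals
    ``gain * exposure_ms * sat(content)``.  Overlapping profiles add; the
    label image assigns contested pixels to the locally brightest nucleus.
    """
    df = _as_content_table(contents)
    n = len(df)
    rng = np.random.default_rng(optics.seed)
    shape = optics.field_shape
    r_mean, r_sd = optics.nucleus_radius_px
    radii = np.maximum(rng.normal(r_mean, r_sd, n), 2.0)
    centres, clumped = _place_nuclei(radii, shape, optics.clump_prob, rng)

    signal = np.zeros(shape, dtype=float)
    best = np.zeros(shape, dtype=float)
    labels = np.zeros(shape, dtype=np.int32)
    totals = (
        optics.gain
        * optics.exposure_ms
        * np.asarray(saturate(df["content"].to_numpy(), optics.saturation_k))
    )
    for i in range(n):
        r = radii[i]
        sigma = r / 3.0
        cr, cc = centres[i]
        lo_r, hi_r = int(math.floor(cr - r)), int(math.ceil(cr + r)) + 1
        lo_c, hi_c = int(math.floor(cc - r)), int(math.ceil(cc + r)) + 1
        yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        dist2 = (yy - cr) ** 2 + (xx - cc) ** 2
        kernel = np.exp(-dist2 / (2.0 * sigma**2))
        kernel[dist2 > r**2] = 0.0
        kernel /= kernel.sum()  # discrete normalisation: mass exactly = total
        contrib = totals[i] * kernel
        win = (slice(lo_r, hi_r), slice(lo_c, hi_c))
        signal[win] += contrib
        take = contrib > best[win]
        labels[win][take] = i + 1
        best[win][take] = contrib[take]

    photons = rng.poisson(signal).astype(float)
    background = rng.normal(
        optics.background_mean, optics.background_sd, shape
    )
    pixels = np.clip(np.rint(photons + background), 0, optics.detector_max)
    image = FieldImage(
        pixels=pixels.astype(np.uint16 if optics.detector_max <= 65535 else np.int64),
        exposure_ms=optics.exposure_ms,
        detector_max=optics.detector_max,
    )
    truth = pd.DataFrame(
        {
            "nucleus_id": np.arange(1, n + 1),
            "phase": df["phase"].to_numpy(),
            "content": df["content"].to_numpy(),
            "centroid_row": centres[:, 0],
            "centroid_col": centres[:, 1],
            "radius_px": radii,
            "clumped": clumped,
        }
    )
    return image, GroundTruthTable(table=truth, labels=labels)


def simulate_dataset(
    mixture: CellCycleMixture,
    optics: OpticsConfig,
    n_nuclei: int,
    seed: int,
) -> list[tuple[FieldImage, GroundTruthTable]]:
    """Render as many fields as needed to cover ``n_nuclei`` cells.

    Fields get independent sub-seeds derived from ``seed``; the last field
    holds the remainder.
    """
    per_field = optics.cells_per_field
    n_fields = math.ceil(n_nuclei / per_field)
    sub = np.random.SeedSequence(seed).generate_state(2 * n_fields) % (2**31)
    out = []
    remaining = n_nuclei
    for f in range(n_fields):
        k = min(per_field, remaining)
        remaining -= k
        contents = sample_dna_contents(mixture, k, int(sub[2 * f]))
        optics_f = replace(optics, seed=int(sub[2 * f + 1]))
        out.append(render_field(contents, optics_f))
    return out


# ---------------------------------------------------------------------------
# Disk I/O: 16-bit single-channel TIFF + YAML sidecar, CSV truth tables.

def write_field(image: FieldImage, path: str | Path, sidecar: bool = True) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image.pixels, dtype=np.uint16))
    if sidecar:
        meta = {
            "exposure_ms": float(image.exposure_ms),
            "detector_max": int(image.detector_max),
            "magnification": image.magnification,
            "dye": image.dye,
        }
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta))


def read_field(
    path: str | Path,
    exposure_ms: float | None = None,
    detector_max: int | None = None,
) -> FieldImage:
    """Read a single-channel TIFF field; sidecar metadata wins over defaults."""
    path = Path(path)
    pixels = tifffile.imread(path)
    meta: dict = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    if detector_max is None:
        detector_max = meta.get(
            "detector_max", int(np.iinfo(pixels.dtype).max) if pixels.dtype.kind == "u" else 65535
        )
    if exposure_ms is None:
        exposure_ms = meta.get("exposure_ms", 1.0)
    return FieldImage(
        pixels=pixels,
        exposure_ms=float(exposure_ms),
        detector_max=int(detector_max),
        magnification=str(meta.get("magnification", "")),
        dye=str(meta.get("dye", "")),
    )


def write_ground_truth(
    truth: GroundTruthTable, csv_path: str | Path, labels_path: str | Path | None = None
) -> None:
    truth.table.to_csv(csv_path, index=False)
    if labels_path is not None:
        tifffile.imwrite(labels_path, truth.labels.astype(np.int32))
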