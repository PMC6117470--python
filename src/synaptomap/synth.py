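"""Ground-truthed synthetic inputs for every pipeline stage.

Each generator is a pure function of its spec plus a seed and emits the
ground truth alongside the artifact, so downstream stages can be scored
without any external data: two-channel punctum images with known centroids
and pairings, mixture-structured parameter tables with planted subtypes,
hierarchical region atlases, and Poisson or bursty spike trains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ImageStack, RegionAtlas

__all__ = [
    "TruthSpec",
    "MixtureSpec",
    "synth_image",
    "synth_param_table",
    "synth_atlas",
    "grid_atlas",
    "synth_spike_trains",
]

PARAM_NAMES = ("intensity", "size_um2", "skewness", "kurtosis", "circularity",
               "aspect_ratio")


@dataclass
class TruthSpec:
    """Specification of a synthetic two-channel punctum image.

    Spots are isotropic 2D Gaussian amplitude profiles (a diffraction-limited
    proxy; the optics resolve ~290 nm FWHM, i.e. sigma ~= 123 nm) with
    heterogeneous lognormal peak amplitudes on a constant background.  Noise
    is Poisson shot noise on the signal plus additive Gaussian read noise.
    A fraction of channel-1 spots receives a channel-2 partner displaced by
    a fixed-radius, uniform-angle offset, which makes the colocalization
    distance rule exactly scorable.

    ``snr`` is peak amplitude (median) divided by the background noise sd
    ``sqrt(background + read_noise**2)``.
    """

    shape_px: tuple[int, int] = (192, 192)
    pixel_size_nm: tuple[float, float] = (84.0, 84.0)
    n_puncta: tuple[int, int] = (130, 130)   # ~0.5 puncta/um^2 at 192 px
    spot_sigma_nm: float = 123.0
    axis_ratio: float = 1.0                  # >1 elongates spots along a random axis
    snr: float = 5.0
    intensity_log_sigma: float = 0.4
    coloc_fraction: float = 0.3
    coloc_offset_nm: float = 100.0
    background: float = 100.0
    read_noise: float = 2.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_puncta) < 0:
            raise ValueError("punctum counts must be nonnegative")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("colocalized fraction must be in [0, 1]")
        sigma_px = self.spot_sigma_nm / max(self.pixel_size_nm)
        if sigma_px < 1.0:
            raise ValueError("spot sigma must be at least 1 pixel after conversion")

    @property
    def noise_sd(self) -> float:
        return float(np.sqrt(self.background + self.read_noise**2))


def _render_spots(shape, centers_px, amps, sigma_px, axis_ratio, angles):
    """Additively render anisotropic Gaussian spots; truncation at 5 sigma."""
    img = np.zeros(shape, dtype=float)
    r = int(np.ceil(5 * sigma_px * max(1.0, axis_ratio)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    for (cy, cx), a, ang in zip(centers_px, amps, angles):
        iy, ix = int(round(cy)), int(round(cx))
        dy = yy + iy - cy
        dx = xx + ix - cx
        # rotate into the spot frame; major axis has sigma*axis_ratio
        ca, sa = np.cos(ang), np.sin(ang)
        u = ca * dx + sa * dy
        v = -sa * dx + ca * dy
        patch = a * np.exp(-(u**2 / (axis_ratio**2) + v**2) / (2 * sigma_px**2))
        y0, y1 = max(0, iy - r), min(shape[0], iy + r + 1)
        x0, x1 = max(0, ix - r), min(shape[1], ix + r + 1)
        img[y0:y1, x0:x1] += patch[y0 - (iy - r):y1 - (iy - r),
                                   x0 - (ix - r):x1 - (ix - r)]
    return img


def synth_image(truth: TruthSpec) -> tuple[ImageStack, pd.DataFrame]:
    """Render a two-channel image and its ground-truth punctum table.

    Returns a stack of shape (2, H, W) (channel axis first) and a table with
    one row per true punctum: ``channel, x_nm, y_nm, amplitude, pair_id``
    (pair_id < 0 marks singletons; partners share a pair_id).
    """
    rng = np.random.default_rng(truth.seed)
    h, w = truth.shape_px
    py, px = truth.pixel_size_nm
    sigma_px = truth.spot_sigma_nm / px
    n1, n2 = truth.n_puncta

    spot_area_um2 = np.pi * (3 * truth.spot_sigma_nm * 1e-3) ** 2
    field_um2 = (h * py * 1e-3) * (w * px * 1e-3)
    if (n1 + n2) * spot_area_um2 > 0.5 * field_um2:
        warnings.warn("requested density implies heavily overlapping spots",
                      stacklevel=2)

    margin = 4 * sigma_px
    def uniform_centers(n):
        return np.column_stack([
            rng.uniform(margin, h - 1 - margin, n),
            rng.uniform(margin, w - 1 - margin, n),
        ])

    c1 = uniform_centers(n1)
    n_pairs = int(round(truth.coloc_fraction * min(n1, n2)))
    # channel-2 partners displaced by a fixed radius at a uniform angle
    theta = rng.uniform(0, 2 * np.pi, n_pairs)
    off_px = np.column_stack([
        truth.coloc_offset_nm / py * np.sin(theta),
        truth.coloc_offset_nm / px * np.cos(theta),
    ])
    c2_pair = c1[:n_pairs] + off_px
    c2_single = uniform_centers(n2 - n_pairs)
    c2 = np.vstack([c2_pair, c2_single]) if n2 else np.empty((0, 2))

    amp_median = truth.snr * truth.noise_sd
    rows = []
    channels_img = []
    for ch, centers in ((0, c1), (1, c2)):
        n = len(centers)
        amps = amp_median * np.exp(rng.normal(0, truth.intensity_log_sigma, n))
        angles = rng.uniform(0, np.pi, n)
        signal = _render_spots((h, w), centers, amps, sigma_px,
                               truth.axis_ratio, angles)
        img = signal + truth.background
        if truth.noise:
            img = rng.poisson(img).astype(float)
            img += rng.normal(0, truth.read_noise, img.shape)
        img = np.clip(np.round(img), 0, 65535).astype(np.uint16)
        channels_img.append(img)
        for i, ((cy, cx), a) in enumerate(zip(centers, amps)):
            if ch == 0:
                pid = i if i < n_pairs else -1
            else:
                pid = i if i < n_pairs else -1
            rows.append(dict(channel=ch, x_nm=cx * px, y_nm=cy * py,
                             x_px=cx, y_px=cy, amplitude=a, pair_id=pid))

    stack = ImageStack(np.stack(channels_img), pixel_size_nm=(py, px))
    table = pd.DataFrame(rows, columns=["channel", "x_nm", "y_nm", "x_px",
                                        "y_px", "amplitude", "pair_id"])
    return stack, table


@dataclass
class MixtureSpec:
    """Planted Gaussian-mixture structure over the punctum measurements.

    The default component counts per type (11 / 7 / 19) mirror the subtype
    catalog structure: puncta expressing only the first marker, only the
    second, or both.  Component means are placed with minimum pairwise
    distance ``separation`` (in within-component sd units, covariance is
    identity unless given), which controls how clusterable the truth is.
    """

    components: dict[int, int] = field(default_factory=lambda: {1: 11, 2: 7, 3: 19})
    dim: int = len(PARAM_NAMES)
    separation: float = 6.0
    weights: dict[int, np.ndarray] | None = None
    covariances: dict[int, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weights is not None:
            for t, w in self.weights.items():
                w = np.asarray(w, float)
                if not np.isclose(w.sum(), 1.0):
                    raise ValueError(f"type {t} weights must sum to 1")
        if self.covariances is not None:
            for t, c in self.covariances.items():
                if np.linalg.eigvalsh(np.asarray(c, float)).min() <= 0:
                    raise ValueError(f"type {t} covariance not positive-definite")


def _separated_means(n, dim, sep, rng):
    """Rejection-sample n points in a cube with min pairwise distance sep."""
    side = sep * max(2.0, n ** (1.0 / dim) + 1.0)
    means = []
    for _ in range(20000):
        cand = rng.uniform(-side / 2, side / 2, dim)
        if all(np.linalg.norm(cand - m) >= sep for m in means):
            means.append(cand)
            if len(means) == n:
                return np.array(means)
    raise RuntimeError("could not place separated component means")


def synth_param_table(mix: MixtureSpec, n: int) -> pd.DataFrame:
    """Draw ``n`` labeled rows from the planted mixture.

    Rows carry true ``type`` and within-type ``component`` labels plus a
    global ``subtype_true`` index (type-1 block first, then 2, then 3).
    Rows per type are allocated proportionally to component counts.
    """
    total_comp = sum(mix.components.values())
    if n < total_comp:
        raise ValueError("n must be at least the total component count")
    rng = np.random.default_rng(mix.seed)
    frames = []
    global_offset = 0
    types = sorted(mix.components)
    n_per_type = {t: int(round(n * mix.components[t] / total_comp)) for t in types}
    n_per_type[types[-1]] += n - sum(n_per_type.values())
    for t in types:
        k = mix.components[t]
        means = _separated_means(k, mix.dim, mix.separation, rng)
        if mix.weights and t in mix.weights:
            w = np.asarray(mix.weights[t], float)
        else:
            w = rng.dirichlet(np.full(k, 5.0))
        cov = None
        if mix.covariances and t in mix.covariances:
            cov = np.asarray(mix.covariances[t], float)
        nt = n_per_type[t]
        comp = rng.choice(k, size=nt, p=w)
        if cov is None:
            x = means[comp] + rng.standard_normal((nt, mix.dim))
        else:
            x = means[comp] + rng.multivariate_normal(
                np.zeros(mix.dim), cov, size=nt)
        df = pd.DataFrame(x, columns=list(PARAM_NAMES)[:mix.dim])
        df.insert(0, "type", t)
        df["component"] = comp
        df["subtype_true"] = comp + 1 + global_offset
        global_offset += k
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "id", np.arange(len(out)))
    return out


def synth_atlas(shape: tuple[int, int], regions: list[dict],
                pixel_size_nm: tuple[float, float] | None = None) -> RegionAtlas:
    """Build a label raster + hierarchy from rectangular region definitions.

    Each region dict needs ``region`` (positive int id), ``parent`` (area
    name) and ``rect`` = (y0, y1, x0, x1) half-open pixel bounds; ``name``
    defaults to ``"R<id>"``.  Overlapping definitions raise.
    """
    labels = np.zeros(shape, dtype=np.int64)
    rows = []
    for spec in regions:
        rid = int(spec["region"])
        if rid <= 0:
            raise ValueError("region ids must be positive")
        y0, y1, x0, x1 = spec["rect"]
        block = labels[y0:y1, x0:x1]
        if (block != 0).any():
            raise ValueError(f"region {rid} overlaps an existing region")
        labels[y0:y1, x0:x1] = rid
        rows.append(dict(region=rid, name=spec.get("name", f"R{rid}"),
                         parent=spec["parent"]))
    hierarchy = pd.DataFrame(rows, columns=["region", "name", "parent"])
    return RegionAtlas(labels, hierarchy, pixel_size_nm)


def grid_atlas(shape: tuple[int, int], n_areas: int, subregions_per_area: int,
               pixel_size_nm: tuple[float, float] | None = None) -> RegionAtlas:
    """Convenience hierarchical atlas: areas are horizontal bands, each split
    into equal vertical subregion strips."""
    h, w = shape
    regions = []
    rid = 1
    for a in range(n_areas):
        y0 = a * h // n_areas
        y1 = (a + 1) * h // n_areas
        for s in range(subregions_per_area):
            x0 = s * w // subregions_per_area
            x1 = (s + 1) * w // subregions_per_area
            regions.append(dict(region=rid, parent=f"A{a + 1}",
                                name=f"A{a + 1}.{s + 1}",
                                rect=(y0, y1, x0, x1)))
            rid += 1
    return synth_atlas(shape, regions, pixel_size_nm)


def synth_spike_trains(rate_hz: float, duration_ms: float, n_trains: int,
                       mode: str = "poisson", seed: int = 0,
                       burst_rate_hz: float = 5.0, pulses_per_burst: int = 4,
                       intra_burst_ipi_ms: float = 10.0) -> list[np.ndarray]:
    """Generate sorted spike-time lists (ms).

    ``poisson`` draws homogeneous Poisson trains at ``rate_hz``; ``burst``
    places Poisson burst onsets at ``burst_rate_hz`` with
    ``pulses_per_burst`` regular pulses each (a theta-burst-like proxy).
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    trains = []
    for _ in range(n_trains):
        if duration_ms <= 0:
            trains.append(np.empty(0))
            continue
        if mode == "poisson":
            n = rng.poisson(rate_hz * duration_ms / 1000.0)
            t = np.sort(rng.uniform(0, duration_ms, n))
        elif mode == "burst":
            n_b = rng.poisson(burst_rate_hz * duration_ms / 1000.0)
            onsets = np.sort(rng.uniform(0, duration_ms, n_b))
            t = (onsets[:, None] + intra_burst_ipi_ms *
                 np.arange(pulses_per_burst)[None, :]).ravel()
            t = np.sort(t[t < duration_ms])
        else:
            raise ValueError(f"unknown spike-train mode {mode!r}")
        trains.append(t)
    return trains
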