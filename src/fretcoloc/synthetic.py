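"""Seeded synthetic microscopy triples with known ground truth.

The generator emulates fields of tissue aggregates (tangle/Lewy-body-like
blobs) imaged in three channels, following the same forward model the
correction assumes::

    rawFRET = d_true * DF + a_true * AF + S_true * (co-located support) + noise

Donor and acceptor objects are discs on a low autofluorescence-like
background.  A configurable fraction of object pairs is co-located
(shared center and radius); inside a co-located pair the per-pixel
intensities of the two channels are drawn from a bivariate normal with a
requested correlation ρ.  Because independent per-channel noise
attenuates pixel correlations, the latent correlation is pre-compensated
analytically so that the *realized* correlation of the emitted pixel
values converges to ρ as the object grows.  Channels are quantized at
the declared bit depth; a ``clip_ceiling`` below the code range
simulates an overexposed acquisition (detector gain raised so the
ceiling maps to full scale), pinning every brighter pixel at
``2**bit_depth - 1`` — exactly the pixels the saturation audit flags.

Objects are hard-edged by default (``edge_sigma = 0``): a fractional-
coverage rim shared by both channels of a pair would add a common
spatial component that inflates the per-object correlation above the
nominal ρ, confounding exactly the quantity the correlated scenarios
exist to probe.  Automated thresholds remain non-trivial because pixel
intensities within objects are heterogeneous.  An optional Gaussian edge
falloff is available for visually softer scenes.

Everything is a pure function of ``(SceneSpec, seed)``.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .io_images import ChannelImage, TripleStack


class GenerationError(RuntimeError):
    """Object packing or parameterization is infeasible."""


@dataclass
class SceneSpec:
    """Parameters of one synthetic field of view.

    Defaults describe a 12-bit confocal field of well-separated bright
    aggregates: mean object intensity 600 with pixel-level spread 100 over
    a background of 30 counts, bleed-through d=0.15 / a=0.05 in the raw
    FRET channel, Poisson shot noise plus a little read noise.
    """

    shape: tuple[int, int] = (512, 512)
    n_objects: int = 60            # per channel (co-located pairs count once in each)
    radius_range: tuple[float, float] = (6.0, 10.0)
    overlap_fraction: float = 0.0  # fraction of pairs sharing center+radius
    intensity_correlation: float = 0.0  # target pixel correlation within co-located pairs
    donor_mean: float = 600.0
    acceptor_mean: float = 600.0
    intensity_sd: float = 100.0    # per-pixel spread inside an object
    amplitude_jitter: float = 0.2  # per-object uniform mean scaling +/- this fraction
    background: float = 30.0       # per-channel background level (counts)
    background_sd: float = 8.0     # amplitude of the shared autofluorescence haze
    haze_scale: float = 8.0        # smoothing length of the haze field (px)
    d_true: float = 0.15
    a_true: float = 0.05
    s_true: float = 0.0            # sensitized-emission amplitude (counts)
    poisson: bool = True
    gaussian_sd: float = 2.0       # additive read noise
    edge_sigma: float = 0.0        # optional Gaussian edge falloff (px)
    bit_depth: int = 12
    # Intensity at which the detector saturates.  The default (2**bit_depth - 1)
    # is correct exposure; a lower ceiling simulates overexposure: the gain is
    # effectively raised so that the ceiling maps to the ADC full scale, and
    # every intensity above it is clipped at 2**bit_depth - 1 (saturated).
    clip_ceiling: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction <= 1:
            raise GenerationError("overlap_fraction must be in [0, 1]")
        if not -1 <= self.intensity_correlation <= 1:
            raise GenerationError("intensity_correlation must be in [-1, 1]")
        if self.clip_ceiling is None:
            self.clip_ceiling = 2**self.bit_depth - 1


@dataclass
class SiteTruth:
    center: tuple[float, float]
    radius: float
    channel: str          # "donor", "acceptor" or "pair"
    realized_correlation: float | None = None


@dataclass
class GroundTruth:
    sites: list[SiteTruth]
    donor_mask: np.ndarray
    acceptor_mask: np.ndarray
    fretc_true: np.ndarray        # the pure sensitized-emission contribution
    d_true: float
    a_true: float
    s_true: float

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "d_true": self.d_true,
            "a_true": self.a_true,
            "s_true": self.s_true,
            "sites": [
                {"center": list(s.center), "radius": s.radius, "channel": s.channel,
                 "realized_correlation": s.realized_correlation}
                for s in self.sites
            ],
        }
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def _place_sites(rng: np.random.Generator, spec: SceneSpec, n_sites: int,
                 margin: float = 3.0, max_attempts: int = 20000) -> list[tuple[float, float, float]]:
    """Random sequential packing of non-overlapping discs; deterministic per rng."""
    rows, cols = spec.shape
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_sites:
        if attempts >= max_attempts:
            raise GenerationError(
                f"could not pack {n_sites} objects of radius <= {spec.radius_range[1]} "
                f"into a {rows}x{cols} field (placed {len(placed)})")
        attempts += 1
        r = rng.uniform(*spec.radius_range)
        cy = rng.uniform(r + 1, rows - r - 1)
        cx = rng.uniform(r + 1, cols - r - 1)
        if all((cy - py) ** 2 + (cx - px) ** 2 >= (r + pr + margin) ** 2
               for py, px, pr in placed):
            placed.append((cy, cx, r))
    return placed


def _disc_weight(shape: tuple[int, int], center: tuple[float, float],
                 radius: float, edge_sigma: float) -> tuple[slice, slice, np.ndarray]:
    """Disc indicator (optionally edge-smoothed) on a bounding-box window."""
    cy, cx, r = center[0], center[1], radius
    pad = int(np.ceil(r + 3 * edge_sigma)) + 1
    r0, r1 = max(0, int(cy) - pad), min(shape[0], int(cy) + pad + 1)
    c0, c1 = max(0, int(cx) - pad), min(shape[1], int(cx) + pad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    w = (dist <= r).astype(float)
    if edge_sigma > 0:
        w = ndi.gaussian_filter(w, sigma=edge_sigma)
    return slice(r0, r1), slice(c0, c1), w


def _latent_correlation(spec: SceneSpec) -> float:
    """Pre-compensate the pair correlation for independent per-channel noise.

    The realized correlation of the final pixel values is the latent
    correlation attenuated by sqrt(sigma^2 / (sigma^2 + nu)) per channel,
    where nu is the independent noise variance (shot noise ~ mean counts,
    plus read noise).  Solving for the latent value and capping at +/-1.
    """
    rho = spec.intensity_correlation
    if rho == 0:
        return 0.0
    s2 = spec.intensity_sd**2
    nu_d = spec.gaussian_sd**2 + (spec.donor_mean + spec.background if spec.poisson else 0.0)
    nu_a = spec.gaussian_sd**2 + (spec.acceptor_mean + spec.background if spec.poisson else 0.0)
    lat = rho * np.sqrt((s2 + nu_d) * (s2 + nu_a)) / s2
    if abs(lat) > 1:
        warnings.warn(
            "noise too strong to realize the requested intensity correlation; "
            "latent correlation capped at +/-1")
        lat = float(np.clip(lat, -1, 1))
    return float(lat)


def generate_scene(spec: SceneSpec, seed: int | None = None) -> tuple[TripleStack, GroundTruth]:
    """Render one triple plus its ground truth; pure function of (spec, seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows, cols = spec.shape

    n_pairs = int(round(spec.overlap_fraction * spec.n_objects))
    # a channel with zero mean intensity is unstained: background only
    n_donor_only = spec.n_objects - n_pairs if spec.donor_mean > 0 else 0
    n_acceptor_only = spec.n_objects - n_pairs if spec.acceptor_mean > 0 else 0
    if n_pairs and (spec.donor_mean == 0 or spec.acceptor_mean == 0):
        raise GenerationError("co-located pairs require both channels stained")
    sites = _place_sites(rng, spec, n_pairs + n_donor_only + n_acceptor_only)
    kinds = ["pair"] * n_pairs + ["donor"] * n_donor_only + ["acceptor"] * n_acceptor_only

    # shared autofluorescence-like haze: a smooth texture present in both
    # stain channels (and, via bleed-through, in rawFRET); it is what excess
    # gain amplifies into false 'yellow' in overexposed acquisitions
    if spec.background_sd > 0:
        haze = ndi.gaussian_filter(rng.standard_normal(spec.shape), spec.haze_scale)
        haze *= spec.background_sd / haze.std()
    else:
        haze = np.zeros(spec.shape)
    base = np.clip(spec.background + haze, 0.0, None)
    donor_f = base.copy()
    acceptor_f = base.copy()
    s_field = np.zeros(spec.shape, dtype=np.float64)
    donor_mask = np.zeros(spec.shape, dtype=bool)
    acceptor_mask = np.zeros(spec.shape, dtype=bool)

    lat = _latent_correlation(spec)
    alpha = np.sqrt(abs(lat))
    truths: list[SiteTruth] = []

    for (cy, cx, r), kind in zip(sites, kinds):
        rsl, csl, w = _disc_weight(spec.shape, (cy, cx), r, spec.edge_sigma)
        support = w > 1e-3
        jd = 1.0 + spec.amplitude_jitter * rng.uniform(-1, 1)
        ja = 1.0 + spec.amplitude_jitter * rng.uniform(-1, 1)
        if kind == "pair":
            z = rng.standard_normal(w.shape)
            ed = rng.standard_normal(w.shape)
            ea = rng.standard_normal(w.shape)
            beta = np.sqrt(max(0.0, 1.0 - alpha**2))
            delta_d = alpha * z + beta * ed
            delta_a = np.sign(lat) * alpha * z + beta * ea if lat != 0 else ea
            donor_f[rsl, csl] += w * np.clip(jd * spec.donor_mean + spec.intensity_sd * delta_d, 0, None)
            acceptor_f[rsl, csl] += w * np.clip(ja * spec.acceptor_mean + spec.intensity_sd * delta_a, 0, None)
            s_field[rsl, csl] += spec.s_true * w
            donor_mask[rsl, csl] |= support
            acceptor_mask[rsl, csl] |= support
        elif kind == "donor":
            delta = rng.standard_normal(w.shape)
            donor_f[rsl, csl] += w * np.clip(jd * spec.donor_mean + spec.intensity_sd * delta, 0, None)
            donor_mask[rsl, csl] |= support
        else:
            delta = rng.standard_normal(w.shape)
            acceptor_f[rsl, csl] += w * np.clip(ja * spec.acceptor_mean + spec.intensity_sd * delta, 0, None)
            acceptor_mask[rsl, csl] |= support
        truths.append(SiteTruth(center=(cy, cx), radius=r, channel=kind))

    rawfret_f = spec.d_true * donor_f + spec.a_true * acceptor_f + s_field

    max_code = 2**spec.bit_depth - 1
    gain = max_code / spec.clip_ceiling  # > 1 only for overexposed acquisition

    def detect(expected: np.ndarray) -> np.ndarray:
        out = rng.poisson(expected).astype(np.float64) if spec.poisson else expected.copy()
        if spec.gaussian_sd > 0:
            out = out + rng.normal(0.0, spec.gaussian_sd, expected.shape)
        return np.clip(np.rint(out * gain), 0, max_code).astype(np.uint16)

    donor_px = detect(donor_f)
    acceptor_px = detect(acceptor_f)
    rawfret_px = detect(rawfret_f)

    # realized pixel correlation within each co-located pair's support
    for (cy, cx, r), kind, truth in zip(sites, kinds, truths):
        if kind != "pair":
            continue
        rsl, csl, w = _disc_weight(spec.shape, (cy, cx), r, spec.edge_sigma)
        core = w >= 0.999
        dvals = donor_px[rsl, csl][core].astype(np.float64)
        avals = acceptor_px[rsl, csl][core].astype(np.float64)
        if dvals.size > 2 and dvals.std() > 0 and avals.std() > 0:
            truth.realized_correlation = float(np.corrcoef(dvals, avals)[0, 1])

    stack = TripleStack(
        ChannelImage(donor_px, spec.bit_depth, "donor"),
        ChannelImage(acceptor_px, spec.bit_depth, "acceptor"),
        ChannelImage(rawfret_px, spec.bit_depth, "rawfret"),
        source_id=f"synthetic-seed{spec.seed if seed is None else seed}",
    )
    truth = GroundTruth(
        sites=truths, donor_mask=donor_mask, acceptor_mask=acceptor_mask,
        fretc_true=s_field, d_true=spec.d_true, a_true=spec.a_true, s_true=spec.s_true,
    )
    return stack, truth


def scenario_library() -> dict[str, SceneSpec]:
    """Named scene specifications mirroring the study conditions.

    * ``distinct_localization`` — donor and acceptor objects spatially
      disjoint, no interaction, correct exposure: the negative-result
      condition.
    * ``overexposed`` — the identical scene clipped at a low ceiling,
      simulating detector saturation (false-positive colocalization).
    * ``true_interaction`` — fully co-located pairs with correlated
      intensities and positive sensitized emission: the positive control.
    * ``donor_only`` / ``acceptor_only`` — single-stain calibration
      controls for the bleed-through factors.
    """
    base = dict(shape=(512, 512), radius_range=(6.0, 10.0), d_true=0.15, a_true=0.05,
                background=30.0, donor_mean=600.0, acceptor_mean=600.0,
                intensity_sd=100.0, bit_depth=12)
    return {
        "distinct_localization": SceneSpec(
            **base, n_objects=60, overlap_fraction=0.0, s_true=0.0,
            poisson=True, gaussian_sd=2.0, seed=11),
        "overexposed": SceneSpec(
            **base, n_objects=60, overlap_fraction=0.0, s_true=0.0,
            poisson=True, gaussian_sd=2.0, clip_ceiling=350, seed=11),
        "true_interaction": SceneSpec(
            **base, n_objects=110, overlap_fraction=1.0, intensity_correlation=0.7,
            s_true=60.0, poisson=False, gaussian_sd=4.0, seed=12),
        "donor_only": SceneSpec(
            **{**base, "acceptor_mean": 0.0}, n_objects=70, s_true=0.0,
            poisson=True, gaussian_sd=2.0, seed=13),
        "acceptor_only": SceneSpec(
            **{**base, "donor_mean": 0.0}, n_objects=70, s_true=0.0,
            poisson=True, gaussian_sd=2.0, seed=14),
    }


def _apply_seed(spec: SceneSpec, seed: int | None) -> SceneSpec:
    if seed is None:
        return spec
    d = asdict(spec)
    d["seed"] = seed
    return SceneSpec(**d)
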