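"""Seeded synthetic dual-probe FISH image generator with full ground truth.

The simulator emulates the single-filter acquisition used in routine HER2
FISH diagnostics: DAPI-counterstained interphase nuclei appear as blue
ellipses on a dark background, HER2 probes as orange diffraction-limited
spots, CEN17 probes as green spots, and strongly amplified nuclei may carry
a HER2 *cluster* — several unresolvable member spots packed into a small
disk.  Every scene is described first as a :class:`SyntheticSpec` (exact
nucleus geometry, planted signal positions, true classes) and only then
rendered, so pixel data, VOC annotations and class labels always agree.

Planted signal counts are chosen so that the scoring rules recover each
nucleus's true class with margin: this is asserted at generation time.
Two quality grades are supported — ``high`` (clean) and ``low`` (extra
blur, noise, attenuated signals, more nucleus overlap) — mirroring the
clean vs blurred/weak/overlapping dichotomy seen in FFPE material.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import (
    AnnotatedObject,
    AnnotationSet,
    BoundingBox,
    NucleusClass,
    SignalClass,
    save_image,
    write_voc,
)
from .scoring import ScoringThresholds, SignalCounts, score_counts

__all__ = [
    "GenerationError",
    "GeneratorConfig",
    "SyntheticNucleus",
    "SyntheticSpec",
    "sample_spec",
    "render",
    "make_dataset",
    "stamp_spot",
    "planted_counts",
]


class GenerationError(RuntimeError):
    """Scene construction failed (e.g. nucleus placement infeasible)."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional knobs of the simulator.

    The class mixture and signal-count ranges define what a "typical"
    diagnostic image looks like; they are deliberately wide of the scoring
    boundaries so each nucleus's class is unambiguous.
    """

    image_size: tuple[int, int] = (1600, 1200)  # (width, height) px
    n_nuclei: tuple[int, int] = (8, 14)         # inclusive range per image
    class_mixture: tuple[tuple[str, float], ...] = (
        ("normal", 0.35), ("low", 0.25), ("high", 0.20),
        ("uncertain", 0.10), ("artifact", 0.10),
    )
    quality: str = "high"                       # "high" (clean) or "low"
    # Geometry
    min_signal_separation: float = 11.0         # px between planted singles
    signal_margin: float = 8.0                  # keep spots this far inside the ellipse
    cluster_radius: float = 12.0                # px, disk holding cluster members
    cluster_members: tuple[int, int] = (4, 6)
    cluster_probability: float = 0.6            # P(cluster | high), else many singles
    overlap_probability: float = 0.0            # P(nucleus deliberately overlaps another)
    # Rendering
    psf_sigma: float = 2.0                      # px, Gaussian spot width
    background_color: tuple[int, int, int] = (5, 5, 20)
    nucleus_color: tuple[int, int, int] = (20, 20, 140)
    her2_color: tuple[int, int, int] = (230, 120, 30)
    cen17_color: tuple[int, int, int] = (40, 220, 40)
    noise_sigma: float = 2.0                    # 8-bit additive noise, clean quality
    # Low-quality degradation
    low_blur_sigma: float = 2.5
    low_noise_sigma: float = 12.0
    low_attenuation: float = 0.4                # fraction of signal amplitude removed
    low_overlap_probability: float = 0.3

    def __post_init__(self) -> None:
        if self.quality not in ("high", "low"):
            raise ValueError(f"quality must be 'high' or 'low', got {self.quality!r}")
        probs = [p for _, p in self.class_mixture]
        if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
            raise ValueError("class mixture must be non-negative and sum to 1")
        if self.n_nuclei[0] < 0 or self.n_nuclei[0] > self.n_nuclei[1]:
            raise ValueError(f"invalid n_nuclei range {self.n_nuclei}")

    @property
    def effective_overlap_probability(self) -> float:
        return self.low_overlap_probability if self.quality == "low" else self.overlap_probability


@dataclass(frozen=True)
class SyntheticNucleus:
    """Ground truth for one nucleus: geometry, planted signals, true class."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation: float
    true_class: NucleusClass
    her2_positions: tuple[tuple[float, float], ...]
    cen17_positions: tuple[tuple[float, float], ...]
    cluster_regions: tuple[tuple[tuple[float, float], float, int], ...]
    #: per cluster region, the member spot positions actually rendered
    cluster_member_positions: tuple[tuple[tuple[float, float], ...], ...] = ()
    overlap_partner: int | None = None

    def bbox_half_extents(self) -> tuple[float, float]:
        """Half width/height of the tight axis-aligned box of the ellipse."""
        a, b = self.semi_axes
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return (
            math.sqrt((a * c) ** 2 + (b * s) ** 2),
            math.sqrt((a * s) ** 2 + (b * c) ** 2),
        )

    def tight_box(self, image_size: tuple[int, int]) -> BoundingBox:
        ex, ey = self.bbox_half_extents()
        cx, cy = self.center
        w, h = image_size
        return BoundingBox(
            max(0, int(math.floor(cx - ex))), max(0, int(math.floor(cy - ey))),
            min(w, int(math.ceil(cx + ex))), min(h, int(math.ceil(cy + ey))),
        )

    def contains(self, x: float, y: float, shrink: float = 0.0) -> bool:
        """Point-in-ellipse test; *shrink* contracts both semi-axes."""
        a, b = self.semi_axes[0] - shrink, self.semi_axes[1] - shrink
        if a <= 0 or b <= 0:
            return False
        dx, dy = x - self.center[0], y - self.center[1]
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        u = dx * c + dy * s
        v = -dx * s + dy * c
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Complete, seeded description of one synthetic scene."""

    image_size: tuple[int, int]
    nuclei: tuple[SyntheticNucleus, ...]
    quality: str
    psf_sigma: float
    seed: int
    config: GeneratorConfig


def planted_counts(nucleus: SyntheticNucleus) -> SignalCounts:
    """Signal counts a perfect detector would report for this nucleus."""
    return SignalCounts(
        n_her2=len(nucleus.her2_positions),
        n_cen17=len(nucleus.cen17_positions),
        n_cluster=len(nucleus.cluster_regions),
    )


# ---------------------------------------------------------------------------
# Scene sampling
# ---------------------------------------------------------------------------

def _sample_counts(
    cls: NucleusClass, rng: np.random.Generator, config: GeneratorConfig
) -> tuple[int, int, int, int]:
    """(n_her2_singles, n_cen17, n_clusters, n_members) for a target class.

    Ranges keep the resulting HER2/CEN17 ratio strictly inside the class's
    interval under the default scoring thresholds, with margin against the
    boundaries so detector noise does not flip the class.
    """
    if cls is NucleusClass.ARTIFACT:
        return int(rng.integers(0, 4)), 0, 0, 0
    if cls is NucleusClass.UNCERTAIN:
        return int(rng.integers(0, 4)), 1, 0, 0
    if cls is NucleusClass.NORMAL:
        cen = int(rng.integers(2, 5))
        # ratio < 1.4 (below the 1.5 boundary with margin)
        her = int(rng.integers(0, int(math.floor(1.35 * cen)) + 1))
        return her, cen, 0, 0
    if cls is NucleusClass.LOW:
        cen = int(rng.integers(2, 4))
        # ratio in [2.0, 5.0]: inside (1.5, 6.0] with margin on both sides
        her = int(rng.integers(2 * cen, 5 * cen + 1))
        return her, cen, 0, 0
    # HIGH: either a cluster, or many singles with ratio in [7, 9]
    cen = int(rng.integers(2, 4))
    if rng.random() < config.cluster_probability:
        members = int(rng.integers(config.cluster_members[0], config.cluster_members[1] + 1))
        extra = int(rng.integers(0, 4))
        return extra, cen, 1, members
    her = int(rng.integers(7 * cen, 9 * cen + 1))
    return her, cen, 0, 0


def _semi_axes_for(
    n_singles: int, has_cluster: bool, rng: np.random.Generator, config: GeneratorConfig
) -> tuple[float, float]:
    """Ellipse semi-axes large enough to hold the planted signals."""
    sep = config.min_signal_separation
    pack_area = 3.0 * max(n_singles, 1) * sep * sep
    inner_area = max(1800.0, pack_area) * rng.uniform(1.05, 1.4)
    q = rng.uniform(0.65, 1.0)
    a_in = math.sqrt(inner_area / (math.pi * q))
    b_in = q * a_in
    if has_cluster:
        need = config.cluster_radius + 6.0
        if b_in < need:
            scale = need / b_in
            a_in *= scale
            b_in *= scale
    m = config.signal_margin
    return (a_in + m, b_in + m)


def _sample_point_in_ellipse(
    nucleus_center: tuple[float, float],
    inner_axes: tuple[float, float],
    rotation: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    t = rng.uniform(0, 2 * math.pi)
    r = math.sqrt(rng.uniform(0, 1))
    u = inner_axes[0] * r * math.cos(t)
    v = inner_axes[1] * r * math.sin(t)
    c, s = math.cos(rotation), math.sin(rotation)
    return (nucleus_center[0] + u * c - v * s, nucleus_center[1] + u * s + v * c)


def _place_signals(
    nucleus_center: tuple[float, float],
    inner_axes: tuple[float, float],
    rotation: float,
    n_her2: int,
    n_cen17: int,
    n_members: int,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> tuple[list, list, list]:
    """Plant signal positions honouring the separation constraints."""
    sep = config.min_signal_separation
    placed: list[tuple[float, float]] = []
    clusters = []
    cluster_center = None

    if n_members:
        ca = max(inner_axes[0] - config.cluster_radius, 1.0)
        cb = max(inner_axes[1] - config.cluster_radius, 1.0)
        cluster_center = _sample_point_in_ellipse(nucleus_center, (ca, cb), rotation, rng)
        members = []
        # members stay within ~70% of the cluster radius and at least 3 px
        # apart: dense enough to be unresolvable, spread enough to form one
        # contiguous accumulation rather than a single bright point
        for _ in range(2000):
            if len(members) == n_members:
                break
            t = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(2.0, 0.7 * config.cluster_radius)
            p = (cluster_center[0] + r * math.cos(t), cluster_center[1] + r * math.sin(t))
            dists = [math.dist(p, q) for q in members]
            touches_chain = not members or min(dists) <= 7.0
            if touches_chain and all(d >= 3.0 for d in dists):
                members.append(p)
        if len(members) < n_members:
            raise GenerationError("could not place cluster members with 3 px separation")
        clusters.append((cluster_center, config.cluster_radius, n_members, tuple(members)))

    def place_batch(n: int) -> list[tuple[float, float]]:
        pts = []
        for _ in range(4000):
            if len(pts) == n:
                break
            p = _sample_point_in_ellipse(nucleus_center, inner_axes, rotation, rng)
            if any(math.dist(p, q) < sep for q in placed + pts):
                continue
            if cluster_center is not None and math.dist(p, cluster_center) < config.cluster_radius + 8.0:
                continue
            pts.append(p)
        if len(pts) < n:
            raise GenerationError(
                f"could not place {n} signals with {sep} px separation inside nucleus"
            )
        return pts

    her2 = place_batch(n_her2)
    placed.extend(her2)
    cen17 = place_batch(n_cen17)
    return her2, cen17, clusters


def sample_spec(config: GeneratorConfig, seed: int) -> SyntheticSpec:
    """Sample a full scene description; identical (config, seed) -> identical spec."""
    rng = np.random.default_rng(seed)
    w, h = config.image_size
    n = int(rng.integers(config.n_nuclei[0], config.n_nuclei[1] + 1))
    classes = [c for c, _ in config.class_mixture]
    probs = [p for _, p in config.class_mixture]

    nuclei: list[SyntheticNucleus] = []
    geoms: list[tuple[tuple[float, float], float]] = []  # (center, bounding radius)
    for i in range(n):
        cls = NucleusClass(str(rng.choice(classes, p=probs)))
        n_her2, n_cen17, n_clusters, n_members = _sample_counts(cls, rng, config)
        semi = _semi_axes_for(n_her2 + n_cen17, n_clusters > 0, rng, config)
        rotation = rng.uniform(0, math.pi)
        rmax = max(semi)

        partner: int | None = None
        want_overlap = bool(geoms) and rng.random() < config.effective_overlap_probability
        center = None
        for attempt in range(300):
            if want_overlap:
                j = int(rng.integers(0, len(geoms)))
                (pjx, pjy), rj = geoms[j]
                t = rng.uniform(0, 2 * math.pi)
                d = 0.75 * (rmax + rj)
                cand = (pjx + d * math.cos(t), pjy + d * math.sin(t))
                partner = j
            else:
                cand = (rng.uniform(rmax + 4, w - rmax - 4), rng.uniform(rmax + 4, h - rmax - 4))
                partner = None
            if not (rmax + 2 <= cand[0] <= w - rmax - 2 and rmax + 2 <= cand[1] <= h - rmax - 2):
                continue
            ok = True
            for j, ((px, py), rj) in enumerate(geoms):
                if partner is not None and j == partner:
                    continue
                if math.dist(cand, (px, py)) < rmax + rj + 4:
                    ok = False
                    break
            if ok:
                center = cand
                break
        if center is None:
            raise GenerationError(
                f"could not place nucleus {i} (radius {rmax:.0f} px) without forbidden overlap"
            )

        inner = (semi[0] - config.signal_margin, semi[1] - config.signal_margin)
        her2, cen17, cluster_full = _place_signals(
            center, inner, rotation, n_her2, n_cen17, n_members, rng, config
        )
        nucleus = SyntheticNucleus(
            center=center,
            semi_axes=semi,
            rotation=rotation,
            true_class=cls,
            her2_positions=tuple(her2),
            cen17_positions=tuple(cen17),
            cluster_regions=tuple((c, r, m) for c, r, m, _ in cluster_full),
            cluster_member_positions=tuple(m for *_, m in cluster_full),
            overlap_partner=partner,
        )
        # generator-side guarantee: the scoring rules recover the true class
        _, recovered = score_counts(planted_counts(nucleus), ScoringThresholds())
        if recovered is not cls:
            raise GenerationError(
                f"planted counts {planted_counts(nucleus)} score as {recovered}, expected {cls}"
            )
        nuclei.append(nucleus)
        geoms.append((center, rmax))

    return SyntheticSpec(
        image_size=config.image_size,
        nuclei=tuple(nuclei),
        quality=config.quality,
        psf_sigma=config.psf_sigma,
        seed=int(seed),
        config=config,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def stamp_spot(
    canvas: np.ndarray,
    x: float,
    y: float,
    sigma: float,
    color: Sequence[float],
) -> None:
    """Add an isotropic Gaussian spot (peak amplitude = *color*) in place."""
    h, w = canvas.shape[:2]
    r = int(math.ceil(4 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    g = np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2.0 * sigma * sigma))
    canvas[y0:y1, x0:x1] += g[..., None] * np.asarray(color, dtype=float)


def _draw_nucleus(canvas: np.ndarray, nucleus: SyntheticNucleus, color: np.ndarray) -> None:
    """Blend an anti-aliased filled ellipse into the canvas."""
    h, w = canvas.shape[:2]
    box = nucleus.tight_box((w, h)).expand(2).clip(w, h)
    ys, xs = np.mgrid[box.y_min:box.y_max, box.x_min:box.x_max]
    dx = xs - nucleus.center[0]
    dy = ys - nucleus.center[1]
    c, s = math.cos(nucleus.rotation), math.sin(nucleus.rotation)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    a, b = nucleus.semi_axes
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    # ~1.5 px anti-aliasing band at the rim
    m = np.clip((1.0 - rho) * (min(a, b) / 1.5), 0.0, 1.0)[..., None]
    region = canvas[box.y_min:box.y_max, box.x_min:box.x_max]
    region[:] = region * (1 - m) + color * m


def render(
    spec: SyntheticSpec,
) -> tuple[np.ndarray, AnnotationSet, list[AnnotationSet]]:
    """Render a spec into (RGB image, nucleus annotations, per-nucleus signal annotations).

    All annotations are in image coordinates.  Signal ground-truth boxes are
    centered on each planted spot with half-size ``3 * psf_sigma``; a cluster
    gets a single ``HER2_cluster`` box covering its disk.
    """
    config = spec.config
    w, h = spec.image_size
    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = np.asarray(config.background_color, dtype=float)

    for nucleus in spec.nuclei:
        _draw_nucleus(canvas, nucleus, np.asarray(config.nucleus_color, dtype=float))

    gain = 1.0 - (config.low_attenuation if spec.quality == "low" else 0.0)
    her2_amp = gain * np.asarray(config.her2_color, dtype=float)
    cen17_amp = gain * np.asarray(config.cen17_color, dtype=float)
    for nucleus in spec.nuclei:
        for (x, y) in nucleus.her2_positions:
            stamp_spot(canvas, x, y, spec.psf_sigma, her2_amp)
        for members in nucleus.cluster_member_positions:
            for (x, y) in members:
                stamp_spot(canvas, x, y, spec.psf_sigma, her2_amp)
        for (x, y) in nucleus.cen17_positions:
            stamp_spot(canvas, x, y, spec.psf_sigma, cen17_amp)

    if spec.quality == "low":
        canvas = gaussian_filter(canvas, sigma=(config.low_blur_sigma, config.low_blur_sigma, 0))
        noise_sd = config.low_noise_sigma
    else:
        noise_sd = config.noise_sigma
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x5EED]))
    canvas += rng.normal(0.0, noise_sd, size=canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    # Ground-truth annotations
    half = int(round(3 * spec.psf_sigma))

    def spot_box(x: float, y: float, extra: float = 0.0) -> BoundingBox:
        e = half + extra
        return BoundingBox(
            max(0, int(round(x - e))), max(0, int(round(y - e))),
            min(w, int(round(x + e))), min(h, int(round(y + e))),
        )

    nucleus_objs = [
        AnnotatedObject(box=nuc.tight_box((w, h)), label=nuc.true_class)
        for nuc in spec.nuclei
    ]
    nuclei_ann = AnnotationSet(
        image_path="", image_size=(w, h), objects=tuple(nucleus_objs), vocabulary="nucleus"
    )

    signal_sets: list[AnnotationSet] = []
    for nuc in spec.nuclei:
        objs = [AnnotatedObject(box=spot_box(x, y), label=SignalClass.HER2)
                for (x, y) in nuc.her2_positions]
        objs += [AnnotatedObject(box=spot_box(x, y), label=SignalClass.CEN17)
                 for (x, y) in nuc.cen17_positions]
        objs += [AnnotatedObject(box=spot_box(cx, cy, extra=radius), label=SignalClass.HER2_CLUSTER)
                 for ((cx, cy), radius, _members) in nuc.cluster_regions]
        signal_sets.append(AnnotationSet(
            image_path="", image_size=(w, h), objects=tuple(objs), vocabulary="signal"
        ))
    return image, nuclei_ann, signal_sets


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _planted_image_grade(spec: SyntheticSpec) -> str:
    """Image grade implied by the planted ground truth (perfect reads)."""
    from .scoring import NucleusRecord, score_image

    records = [
        NucleusRecord.from_counts(i, planted_counts(nuc), nd_class=nuc.true_class)
        for i, nuc in enumerate(spec.nuclei)
    ]
    return str(score_image(records).final_call)


def child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-image seeds derived from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def make_dataset(
    config: GeneratorConfig,
    n_images: int,
    seed: int,
    out_dir: str | Path,
) -> Path:
    """Write *n_images* rendered scenes with VOC annotations and a manifest.

    Per image: ``image_XXX.png``, ``image_XXX.xml`` (nucleus boxes) and one
    ``image_XXX_n<k>_signals.xml`` per nucleus (signal boxes, image
    coordinates).  The manifest is a TSV (image, n_nuclei, true_grade, seed)
    whose true grades are computed by the scoring module from the planted
    counts.  Returns the manifest path.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(child_seeds(seed, n_images)):
        spec = sample_spec(config, s)
        image, nuclei_ann, signal_sets = render(spec)
        stem = f"image_{i:03d}"
        save_image(image, out_dir / f"{stem}.png")
        write_voc(replace(nuclei_ann, image_path=f"{stem}.png"), out_dir / f"{stem}.xml")
        for k, sig in enumerate(signal_sets):
            write_voc(
                replace(sig, image_path=f"{stem}.png"),
                out_dir / f"{stem}_n{k:02d}_signals.xml",
            )
        rows.append((f"{stem}.png", len(spec.nuclei), _planted_image_grade(spec), s))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("image\tn_nuclei\ttrue_grade\tseed\n")
        for name, n_nuc, grade, s in rows:
            fh.write(f"{name}\t{n_nuc}\t{grade}\t{s}\n")
    return manifest


def dataset_checksum(directory: str | Path) -> str:
    """SHA-256 over all PNG/XML/TSV bytes in a dataset directory (sorted order)."""
    digest = hashlib.sha256()
    for path in sorted(Path(directory).iterdir()):
        if path.suffix in (".png", ".xml", ".tsv"):
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
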