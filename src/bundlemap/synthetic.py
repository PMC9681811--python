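"""Synthetic bundle-map generators with known ground truth.

Five pattern families span the regularity spectrum the analysis has to
discriminate: homogeneous Poisson (complete spatial randomness), jittered
hexagonal lattices (maximal regularity), Matern type-II hard-core patterns
(regular but not crystalline), banded string patterns emulating the thin
curving and branched bands that myelin bundles actually form in tangential
sections, and linear-gradient inhomogeneous Poisson patterns emulating the
smooth ~2x density drifts seen across a few mm of cortex.  A shifted-gamma
sampler produces 1-D inter-bundle distance sequences matched to target
mean / SD / skewness, optionally with AR(1) positional autocorrelation.

All generators take intensities in bundles/mm^2 (coordinates in um) and a
single integer seed; fixed seed implies bit-reproducible output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .patterns import UM2_PER_MM2, PointPattern, Window

# random sequential adsorption jamming fraction for congruent hard disks;
# used as the feasibility bound for the hard-core thinning parameters
DISK_JAMMING_FRACTION = 0.5472


def _check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def gen_poisson(intensity_per_mm2: float, window: Window, seed: int) -> PointPattern:
    """Homogeneous Poisson pattern — the complete-spatial-randomness benchmark.

    Parameters
    ----------
    intensity_per_mm2 : expected density in bundles/mm^2.
    window : analysis window (um).
    seed : integer seed; fixed seed gives bit-identical output.
    """
    if intensity_per_mm2 < 0 or not np.isfinite(intensity_per_mm2):
        raise ValueError(f"intensity must be non-negative, got {intensity_per_mm2!r}")
    rng = np.random.default_rng(seed)
    lam = intensity_per_mm2 / UM2_PER_MM2  # points/um^2
    n = rng.poisson(lam * window.area)
    x = rng.uniform(window.x_min, window.x_max, n)
    y = rng.uniform(window.y_min, window.y_max, n)
    return PointPattern(np.column_stack([x, y]), window, label="poisson")


def gen_hex_lattice(
    spacing: float, window: Window, jitter_sd: float = 0.0, seed: int = 0
) -> PointPattern:
    """Triangular (hexagonal-packing) lattice clipped to the window.

    With ``jitter_sd == 0`` every interior point has six nearest neighbours at
    exactly ``spacing`` and the density is 2 / (sqrt(3) * spacing^2).  Jittered
    points are reflected at the window edges so the count is preserved.
    """
    _check_positive("spacing", spacing)
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    dy = spacing * np.sqrt(3.0) / 2.0
    if spacing > window.width or dy > window.height:
        warnings.warn("lattice spacing exceeds window extent; pattern may be empty")
    rows = []
    k = 0
    while True:
        y = window.y_min + (k + 0.5) * dy
        if y >= window.y_max:
            break
        offset = 0.5 * spacing if (k % 2) else 0.0
        x = np.arange(window.x_min + 0.25 * spacing + offset, window.x_max, spacing)
        rows.append(np.column_stack([x, np.full_like(x, y)]))
        k += 1
    pts = np.vstack(rows) if rows else np.empty((0, 2))
    if jitter_sd > 0 and pts.size:
        rng = np.random.default_rng(seed)
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
        pts[:, 0] = _reflect(pts[:, 0], window.x_min, window.x_max)
        pts[:, 1] = _reflect(pts[:, 1], window.y_min, window.y_max)
    return PointPattern(pts, window, label="hex_lattice")


def _reflect(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (assumes excursions < window size)."""
    v = np.where(v < lo, 2 * lo - v, v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, lo, hi)


def matern2_retained_intensity(parent_per_mm2: float, min_dist: float) -> float:
    """Closed-form retained intensity of Matern type-II thinning (bundles/mm^2).

    lambda_ret = (1 - exp(-lambda_p * pi * h^2)) / (pi * h^2).
    """
    lam_p = parent_per_mm2 / UM2_PER_MM2
    disc = np.pi * min_dist**2
    return (1.0 - np.exp(-lam_p * disc)) / disc * UM2_PER_MM2


def gen_hardcore(
    intensity_per_mm2: float, min_dist: float, window: Window, seed: int
) -> PointPattern:
    """Matern type-II hard-core pattern: no two points closer than ``min_dist``.

    Proposals come from a Poisson parent of the given intensity with i.i.d.
    uniform marks; a proposal is deleted when any neighbour within
    ``min_dist`` carries an earlier (smaller) mark.  The parent is drawn on a
    window buffered by ``min_dist`` and clipped after thinning, so retention
    near the edges is not biased by missing competitors.
    """
    _check_positive("intensity", intensity_per_mm2)
    _check_positive("min_dist", min_dist)
    packing = (intensity_per_mm2 / UM2_PER_MM2) * np.pi * min_dist**2 / 4.0
    if packing >= DISK_JAMMING_FRACTION:
        raise ValueError(
            f"infeasible hard-core parameters: parent intensity x pi h^2/4 = "
            f"{packing:.3f} exceeds the disk jamming fraction "
            f"{DISK_JAMMING_FRACTION}"
        )
    rng = np.random.default_rng(seed)
    buf = Window(
        window.x_min - min_dist,
        window.x_max + min_dist,
        window.y_min - min_dist,
        window.y_max + min_dist,
    )
    lam = intensity_per_mm2 / UM2_PER_MM2
    n = rng.poisson(lam * buf.area)
    pts = np.column_stack(
        [rng.uniform(buf.x_min, buf.x_max, n), rng.uniform(buf.y_min, buf.y_max, n)]
    )
    marks = rng.uniform(size=n)
    keep = np.ones(n, dtype=bool)
    if n:
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        pairs = tree.query_pairs(min_dist, output_type="ndarray")
        for i, j in pairs:
            if marks[i] < marks[j]:
                keep[j] = False
            else:
                keep[i] = False
    pts = pts[keep]
    pts = pts[window.contains(pts)]
    return PointPattern(pts, window, label="hardcore")


def gen_banded(
    band_spacing: float,
    along_spacing: float,
    wobble: float,
    window: Window,
    seed: int,
    wobble_wavelength: float = 400.0,
    branch_prob_per_um: float = 0.0,
) -> PointPattern:
    """Quasi-parallel curving strings of bundles separated by broader bands.

    Strings run along x at nominal y-pitch ``band_spacing``, each perturbed
    sinusoidally with amplitude ``wobble`` (um), wavelength
    ``wobble_wavelength`` and an independent random phase, so neighbouring
    strings drift together and apart the way bundle bands do in tangential
    sections.  Points sit every ``along_spacing`` um along each string.
    Branching (a string forking into the inter-band gap) is off by default;
    ``branch_prob_per_um`` enables it.
    """
    _check_positive("band_spacing", band_spacing)
    _check_positive("along_spacing", along_spacing)
    if wobble < 0:
        raise ValueError("wobble must be >= 0")
    if not band_spacing > along_spacing:
        warnings.warn(
            "band_spacing <= along_spacing does not reproduce the observed "
            "band morphology (strings closer than their internal spacing)"
        )
    rng = np.random.default_rng(seed)
    omega = 2.0 * np.pi / wobble_wavelength
    all_pts = []

    def _string(y0: float, phase: float, x_start: float) -> None:
        xs = np.arange(x_start, window.x_max, along_spacing)
        ys = y0 + wobble * np.sin(omega * xs + phase)
        pts = np.column_stack([xs, ys])
        all_pts.append(pts[window.contains(pts)])
        if branch_prob_per_um > 0:
            n_branch = rng.poisson(branch_prob_per_um * max(window.width, 0.0))
            for _ in range(n_branch):
                bx = rng.uniform(window.x_min, window.x_max)
                by = y0 + wobble * np.sin(omega * bx + phase)
                length = rng.uniform(2, 6) * along_spacing
                bxs = np.arange(bx, min(bx + length, window.x_max), along_spacing)
                bys = by + (bxs - bx) * rng.choice([-1.0, 1.0]) * 0.5
                bpts = np.column_stack([bxs, bys])
                all_pts.append(bpts[window.contains(bpts)])

    if band_spacing >= window.height:
        # degenerate single-band case: one string through the window middle
        _string(
            (window.y_min + window.y_max) / 2.0,
            rng.uniform(0, 2 * np.pi) if wobble > 0 else 0.0,
            window.x_min,
        )
    else:
        y = window.y_min + rng.uniform(0, band_spacing)
        while y < window.y_max + wobble:
            phase = rng.uniform(0, 2 * np.pi)
            x_start = window.x_min + rng.uniform(0, along_spacing)
            _string(y, phase, x_start)
            y += band_spacing
    pts = np.vstack(all_pts) if all_pts else np.empty((0, 2))
    return PointPattern(pts, window, label="banded")


def gen_gradient_poisson(
    base_per_mm2: float,
    gradient_ratio: float,
    window: Window,
    seed: int,
    axis: str = "x",
) -> PointPattern:
    """Inhomogeneous Poisson pattern with intensity rising linearly along an axis.

    Intensity runs from ``base_per_mm2`` at the low edge to
    ``base_per_mm2 * gradient_ratio`` at the high edge; realised by thinning a
    homogeneous parent at the peak intensity (keep probability lambda(u)/max).
    """
    _check_positive("base intensity", base_per_mm2)
    if gradient_ratio < 1:
        raise ValueError("gradient_ratio must be >= 1")
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    parent = gen_poisson(base_per_mm2 * gradient_ratio, window, seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 1]))
    if axis == "x":
        t = (parent.points[:, 0] - window.x_min) / window.width
    else:
        t = (parent.points[:, 1] - window.y_min) / window.height
    keep_prob = (1.0 + (gradient_ratio - 1.0) * t) / gradient_ratio
    keep = rng.uniform(size=parent.n) < keep_prob
    return PointPattern(parent.points[keep], window, label="gradient_poisson")


@dataclass(frozen=True)
class DistanceGenConfig:
    """Targets for a synthetic inter-bundle distance sequence.

    ``mean``/``sd`` in um, ``skewness`` dimensionless; ``ar1`` adds first-order
    positional autocorrelation (on ranks) to emulate smooth spacing gradients
    along a cortical traverse.
    """

    n: int
    mean: float
    sd: float
    skewness: float = 0.0
    bin_width: float = 5.0
    seed: int = 0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        _check_positive("mean", self.mean)
        _check_positive("sd", self.sd)
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must be in [0, 1)")


def gen_distance_sequence(config: DistanceGenConfig) -> np.ndarray:
    """Draw an ordered distance sequence from a shifted-gamma (or Gaussian) family.

    Method-of-moments mapping for skewness > 0:
    shape k = 4/skew^2, scale theta = sd*skew/2, shift = mean - k*theta.
    skewness == 0 uses a Gaussian.  A negative support shift (skewness too
    large for the given mean/sd) is rejected.
    """
    rng = np.random.default_rng(config.seed)
    if config.skewness < 0:
        raise ValueError("skewness must be >= 0")
    if config.skewness == 0:
        values = rng.normal(config.mean, config.sd, config.n)
        if np.any(values <= 0):
            values = np.abs(values)  # distances are strictly positive
    else:
        k = 4.0 / config.skewness**2
        theta = config.sd * config.skewness / 2.0
        shift = config.mean - k * theta
        if shift < 0:
            raise ValueError(
                f"shifted-gamma support would start at {shift:.2f} < 0; "
                "lower the skewness target for this mean/sd"
            )
        values = shift + rng.gamma(k, theta, config.n)
    if config.ar1 > 0:
        # impose positional autocorrelation by re-ordering the draws to the
        # rank order of an AR(1) Gaussian series (marginals unchanged)
        z = np.empty(config.n)
        eps = rng.normal(size=config.n)
        z[0] = eps[0]
        for i in range(1, config.n):
            z[i] = config.ar1 * z[i - 1] + np.sqrt(1 - config.ar1**2) * eps[i]
        values = np.sort(values)[np.argsort(np.argsort(z))]
    return values


@dataclass(frozen=True)
class GeneratorConfig:
    """Declarative generator request used by the pipeline/CLI layer."""

    kind: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    KINDS = ("poisson", "hex_lattice", "hardcore", "banded", "gradient_poisson")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; one of {self.KINDS}")


def generate(config: GeneratorConfig, window: Window) -> PointPattern:
    """Dispatch a :class:`GeneratorConfig` to the matching generator."""
    p = dict(config.parameters)
    if config.kind == "poisson":
        return gen_poisson(p["intensity_per_mm2"], window, config.seed)
    if config.kind == "hex_lattice":
        return gen_hex_lattice(
            p["spacing"], window, p.get("jitter_sd", 0.0), config.seed
        )
    if config.kind == "hardcore":
        return gen_hardcore(p["intensity_per_mm2"], p["min_dist"], window, config.seed)
    if config.kind == "banded":
        return gen_banded(
            p["band_spacing"],
            p["along_spacing"],
            p.get("wobble", 16.0),
            window,
            config.seed,
            wobble_wavelength=p.get("wobble_wavelength", 400.0),
            branch_prob_per_um=p.get("branch_prob_per_um", 0.0),
        )
    if config.kind == "gradient_poisson":
        return gen_gradient_poisson(
            p["base_per_mm2"],
            p.get("gradient_ratio", 1.0),
            window,
            config.seed,
            axis=p.get("axis", "x"),
        )
    raise AssertionError("unreachable")
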