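"""Synthetic fingerprint generation with known ground truth.

Stands in for the closed SFinGe generator: an orientation field built from
the Sherlock-Monro zero-pole model (cores are zeros contributing +1/2 to the
Poincare index, deltas poles contributing -1/2) drives either a direct phase
render (singularity-free patterns) or iterated oriented filtering of a seeded
init (loops/whorls), producing a gray image, its ground-truth single-pixel
skeleton, and the traced ridges. Simple grating / concentric-arc / Y-junction
skeleton fixtures for controlled experiments live here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.signal import fftconvolve
from skimage.draw import line as draw_line
from skimage.morphology import skeletonize

from .bezier import Ridge, extract_ridges, prune_skeleton
from .damage import DamageSpec, simulate_damage
from .preprocess import remove_2x2_blocks

PATTERNS = ("plain-arch", "tented-arch", "left-loop", "right-loop", "whorl")


@dataclass
class PatternSpec:
    pattern: str = "plain-arch"
    size: tuple = (300, 300)
    ridge_period: float = 8.0
    singular_points: list | None = None  # [(kind, (row, col)), ...]
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 6.0 <= self.ridge_period <= 12.0:
            raise ValueError("ridge_period must lie in [6, 12] px")
        if self.singular_points is None:
            self.singular_points = default_singular_points(self.pattern, self.size)
        cores = sum(1 for k, _ in self.singular_points if k == "core")
        deltas = sum(1 for k, _ in self.singular_points if k == "delta")
        expect = {"plain-arch": (0, 0), "tented-arch": (1, 1),
                  "left-loop": (1, 1), "right-loop": (1, 1), "whorl": (2, 2)}
        if (cores, deltas) != expect[self.pattern]:
            raise ValueError(f"{self.pattern} expects {expect[self.pattern]} "
                             f"(cores, deltas), got {(cores, deltas)}")


@dataclass
class SyntheticSample:
    image: np.ndarray
    true_skeleton: np.ndarray
    true_mask: np.ndarray
    true_ridges: list
    spec: PatternSpec

    @property
    def ablated_skeleton(self) -> np.ndarray:
        return (self.true_skeleton.astype(bool) & ~self.true_mask.astype(bool)).astype(np.uint8)


def default_singular_points(pattern: str, size: tuple) -> list:
    h, w = size
    if pattern == "plain-arch":
        return []
    if pattern == "tented-arch":
        return [("core", (0.45 * h, 0.50 * w)), ("delta", (0.82 * h, 0.50 * w))]
    if pattern == "left-loop":
        return [("core", (0.40 * h, 0.45 * w)), ("delta", (0.78 * h, 0.68 * w))]
    if pattern == "right-loop":
        return [("core", (0.40 * h, 0.55 * w)), ("delta", (0.78 * h, 0.32 * w))]
    # whorl
    return [("core", (0.40 * h, 0.50 * w)), ("core", (0.55 * h, 0.50 * w)),
            ("delta", (0.82 * h, 0.22 * w)), ("delta", (0.82 * h, 0.78 * w))]


def _arch_phase(spec: PatternSpec) -> np.ndarray:
    """Scalar phase field whose level sets are arched ridges."""
    h, w = spec.size
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    amp = 0.22 * h
    sigma = 0.30 * w
    bump = amp * np.exp(-((cc - w / 2.0) ** 2) / (2 * sigma**2))
    return rr + bump


def orientation_field(spec: PatternSpec) -> np.ndarray:
    """Ridge-orientation grid (radians, mod pi) for the given pattern.

    Patterns with singular points use the zero-pole model
    theta(z) = theta0 + 1/2 sum arg(z - core) - 1/2 sum arg(z - delta);
    the plain arch derives its (singularity-free) orientation from the
    gradient of the arch phase field.
    """
    h, w = spec.size
    if not spec.singular_points:
        psi = _arch_phase(spec)
        gr, gc = np.gradient(psi)
        return np.mod(np.arctan2(gr, gc) + np.pi / 2, np.pi)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    theta = np.zeros((h, w))
    for kind, (pr, pc) in spec.singular_points:
        ang = np.arctan2(rr - pr, cc - pc)
        theta += 0.5 * ang if kind == "core" else -0.5 * ang
    return np.mod(theta, np.pi)


def poincare_index(field: np.ndarray, pos, radius: int = 6) -> float:
    """Numeric Poincare index of an orientation field around ``pos``."""
    pr, pc = pos
    n = 32
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rs = np.clip(np.round(pr + radius * np.sin(ang)).astype(int), 0, field.shape[0] - 1)
    cs = np.clip(np.round(pc + radius * np.cos(ang)).astype(int), 0, field.shape[1] - 1)
    th = field[rs, cs]
    d = np.diff(np.concatenate([th, th[:1]]))
    d = (d + np.pi / 2) % np.pi - np.pi / 2  # wrap to (-pi/2, pi/2]
    return float(d.sum() / (2 * np.pi))


def _oriented_kernel(theta: float, period: float) -> np.ndarray:
    sigma = 0.5 * period
    half = int(np.ceil(2.5 * sigma))
    rr, cc = np.mgrid[-half:half + 1, -half:half + 1]
    dr, dc = np.sin(theta), np.cos(theta)
    along = rr * dr + cc * dc
    across = -rr * dc + cc * dr
    env = np.exp(-0.5 * (across**2 + along**2) / sigma**2)
    k = env * np.cos(2 * np.pi * across / period)
    return k - k.sum() / k.size


def _iterate_stripes(field: np.ndarray, spec: PatternSpec, rng) -> np.ndarray:
    """Evolve seeded stripes under oriented filtering until they follow the field."""
    h, w = spec.size
    rr = np.mgrid[0:h, 0:w][0].astype(float)
    x = np.cos(2 * np.pi * rr / spec.ridge_period) + 0.5 * rng.standard_normal((h, w))
    nbin = 16
    bins = np.floor(field / np.pi * nbin).astype(int) % nbin
    kernels = [_oriented_kernel((b + 0.5) * np.pi / nbin, spec.ridge_period)
               for b in range(nbin)]
    for _ in range(6):
        resp = np.zeros_like(x)
        for b in range(nbin):
            sel = bins == b
            if sel.any():
                resp[sel] = fftconvolve(x, kernels[b], mode="same")[sel]
        norm = np.abs(resp).max()
        x = np.tanh(3.0 * resp / max(norm, 1e-9))
    return x


def render_ridges(field: np.ndarray, spec: PatternSpec) -> SyntheticSample:
    """Render a gray fingerprint (ridges dark) plus its ground-truth skeleton."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    if not spec.singular_points:
        psi = _arch_phase(spec)
        stripe = np.cos(2 * np.pi * psi / spec.ridge_period)
    else:
        stripe = _iterate_stripes(field, spec, rng)
    ridge_mask = stripe > 0.2
    skel = remove_2x2_blocks(skeletonize(ridge_mask, method="zhang")).astype(np.uint8)
    skel = prune_skeleton(skel, min_branch_len=6)
    gray = 128.0 - 100.0 * np.clip(stripe, -1, 1)
    if spec.noise_level > 0:
        gray = gray + spec.noise_level * 128.0 * rng.standard_normal((h, w))
    gray = np.clip(gray, 0, 255)
    return SyntheticSample(image=gray, true_skeleton=skel,
                           true_mask=np.zeros((h, w), np.uint8),
                           true_ridges=extract_ridges(skel), spec=spec)


def generate(spec: PatternSpec) -> SyntheticSample:
    return render_ridges(orientation_field(spec), spec)


def make_dataset(specs: list[PatternSpec], damage_specs: list[DamageSpec | None],
                 seed: int = 0) -> list[SyntheticSample]:
    """Cartesian specs x damage with derived per-sample seeds."""
    out = []
    idx = 0
    for spec in specs:
        for dmg in damage_specs:
            sub = (seed * 1009 + idx * 9176 + spec.seed) % (2**31 - 1)
            s = PatternSpec(pattern=spec.pattern, size=spec.size,
                            ridge_period=spec.ridge_period,
                            singular_points=list(spec.singular_points) or None,
                            noise_level=spec.noise_level, seed=sub)
            if not spec.singular_points:
                s.singular_points = []
            sample = generate(s)
            if dmg is not None:
                img, mask = simulate_damage(sample.image, dmg, seed=sub)
                sample = SyntheticSample(image=img, true_skeleton=sample.true_skeleton,
                                         true_mask=mask.astype(np.uint8),
                                         true_ridges=sample.true_ridges, spec=s)
            out.append(sample)
            idx += 1
    return out


# --------------------------------------------------------------------------
# skeleton-level fixtures for controlled experiments


def grating_skeleton(shape=(128, 128), period: int = 8, margin: int = 4,
                     vertical: bool = False) -> np.ndarray:
    """Parallel single-pixel ridges at the given spacing."""
    h, w = shape
    out = np.zeros(shape, np.uint8)
    if vertical:
        for c in range(margin + period // 2, w - margin, period):
            out[margin:h - margin, c] = 1
    else:
        for r in range(margin + period // 2, h - margin, period):
            out[r, margin:w - margin] = 1
    return out


def arc_skeleton(shape=(160, 160), period: int = 8, center=None,
                 n_arcs: int | None = None) -> np.ndarray:
    """Concentric single-pixel circular arcs around ``center``."""
    h, w = shape
    center = center if center is not None else (h - 4, w // 2)
    rr, cc = np.mgrid[0:h, 0:w].astype(float)
    rho = np.hypot(rr - center[0], cc - center[1])
    max_r = rho.max() if n_arcs is None else period * (n_arcs + 1)
    band = (np.cos(2 * np.pi * rho / period) > 0.4) & (rho < max_r)
    return remove_2x2_blocks(skeletonize(band, method="zhang")).astype(np.uint8)


def y_skeleton(shape=(96, 128), period: int = 8, split_col: int | None = None):
    """A ridge that bifurcates, embedded in a field of conforming neighbors.

    Returns (skeleton, bifurcation point (row, col)). The central ridge runs
    along the middle row and splits at ``split_col`` into two branches that
    diverge at slope 1/4 until they sit half a period off-axis (so the final
    branch separation equals the ridge period). Neighboring ridges follow the
    same divergence envelope, keeping inter-ridge spacing constant everywhere
    — as around a real bifurcation — so damage detection sees no spurious
    gaps.
    """
    h, w = shape
    split_col = split_col if split_col is not None else w // 2
    mid = h // 2
    margin = 4
    out = np.zeros(shape, np.uint8)
    dmax = period / 2.0

    def envelope(c):
        return min(dmax, max(0.0, (c - split_col) * 0.25))

    def draw_path(rows_cols):
        prev = None
        for r, c in rows_cols:
            r = int(round(r))
            if not 0 <= r < h:
                prev = None
                continue
            if prev is not None:
                rr, cc = draw_line(prev[0], prev[1], r, c)
                out[rr, cc] = 1
            else:
                out[r, c] = 1
            prev = (r, c)

    cols = range(margin, w - margin)
    n_side = (h // 2 - margin) // period
    for k in range(1, n_side + 1):
        # the divergence disturbance decays away from the bifurcating ridge,
        # as in a real orientation field, keeping the pattern's outer
        # boundary straight
        decay = 0.5**k
        for sgn in (-1, 1):
            draw_path([(mid + sgn * (k * period + decay * envelope(c)), c)
                       for c in cols])
    # the bifurcating central ridge: single track, then two branches
    draw_path([(mid, c) for c in range(margin, split_col + 1)])
    for sgn in (-1, 1):
        draw_path([(mid + sgn * envelope(c), c) for c in range(split_col, w - margin)])
    return remove_2x2_blocks(out.astype(bool)).astype(np.uint8), (mid, split_col)


def disk_mask(shape, center, radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return np.hypot(rr - center[0], cc - center[1]) <= radius


def ablate(skel: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove skeleton pixels under a damage mask (ground-truth ablation)."""
    return (np.asarray(skel).astype(bool) & ~np.asarray(mask).astype(bool)).astype(np.uint8)
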