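"""CT-patch layer: segmentation, seeding, HU remapping and MLD scoring.

Connects the coupled tissue simulation to 2D CT patches in Hounsfield
units (HU).  Parenchyma is segmented with a fixed -750 HU threshold (the
air-rich, low-attenuation side).  Stereology gives about 170 alveoli per
cubic millimeter of parenchyma, i.e. roughly 130 alveoli in one
0.78 x 0.78 x 1.25 mm CT voxel; each "affected" voxel therefore runs one
coupled simulation on a planar grid of that many alveolar units.  The
resulting mean element stiffness is translated linearly back into HU
(healthy modulus keeps the original value, a fully destroyed voxel
approaches air at -1000 HU), which reproduces the characteristic darkening
of emphysematous parenchyma.  Progression is scored with the Mean Lung
Density (MLD): the mean HU over the parenchyma mask.

A seeded synthetic patch generator stands in for real CT data: textured
parenchyma with sparse bright vessel streaks, plus growing clusters of
low-attenuation "holes" for the moderate and severe classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .abm import ABConfig, SmokingSignal, init_grid
from .coupling import CouplingConfig, run_coupled
from .mechanics import BreathingLoad, mixture_modulus
from .wm_model import ImmuneParams

__all__ = [
    "HU_AIR", "HU_MIN", "HU_MAX", "E0_HEALTHY",
    "CTPatch", "ParenchymaMask", "SeedSet",
    "segment_parenchyma", "alveoli_per_voxel", "select_seeds",
    "grid_for_voxel", "modulus_to_hu", "mld", "synth_patch",
    "group_compare", "simulate_progression", "load_patch",
]

HU_AIR = -1000.0
HU_MIN, HU_MAX = -1024.0, 3071.0
#: Young's modulus of fully healthy tissue (cel = ccl = 1), Pa.
E0_HEALTHY = float(mixture_modulus(1.0, 1.0, True))

SEVERITIES = ("healthy", "moderate", "severe", "none")


@dataclass
class CTPatch:
    """Square 2D CT patch in Hounsfield units with physical spacing."""

    hu: np.ndarray
    spacing: tuple[float, float] = (0.78, 0.78)  # mm
    thickness: float = 1.25                       # mm
    severity: str = "none"

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 2 or self.hu.shape[0] != self.hu.shape[1]:
            raise ValueError("patch must be a square 2D array")
        if np.any(self.hu < HU_MIN) or np.any(self.hu > HU_MAX):
            raise ValueError(f"HU values must lie in [{HU_MIN}, {HU_MAX}]")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")

    def copy(self) -> "CTPatch":
        return CTPatch(self.hu.copy(), self.spacing, self.thickness,
                       self.severity)


@dataclass
class ParenchymaMask:
    """Boolean parenchyma mask congruent with its patch."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class SeedSet:
    """Affected pixels: sampled seeds plus their in-mask 4-neighbors."""

    pixels: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pixels)


def segment_parenchyma(patch: CTPatch, threshold: float = -750.0) -> ParenchymaMask:
    """Threshold segmentation: parenchyma is the air-rich side (HU <= threshold)."""
    return ParenchymaMask(patch.hu <= threshold)


def alveoli_per_voxel(
    spacing: tuple[float, float] = (0.78, 0.78),
    thickness: float = 1.25,
    density: float = 170.0,
) -> int:
    """Alveoli contained in one CT voxel, rounded to the nearest ten.

    ``density`` is the stereological mean alveolar density (per mm^3).
    """
    if spacing[0] <= 0 or spacing[1] <= 0 or thickness <= 0:
        raise ValueError("voxel dimensions must be positive")
    volume = spacing[0] * spacing[1] * thickness
    return int(round(density * volume / 10.0) * 10)


def select_seeds(
    mask: ParenchymaMask,
    n: int = 200,
    seed: int | np.random.Generator = 0,
) -> SeedSet:
    """Sample ``n`` parenchyma pixels and expand by in-mask 4-neighbors.

    Seeds are drawn uniformly without replacement; if the mask holds fewer
    than ``n`` pixels, all of them are used (with a warning).  The result
    is deduplicated and sorted for reproducibility.
    """
    coords = np.argwhere(mask.mask)
    if coords.shape[0] == 0:
        raise ValueError("empty parenchyma mask")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if coords.shape[0] < n:
        warnings.warn(f"mask has only {coords.shape[0]} pixels; using all",
                      stacklevel=2)
        picked = coords
    else:
        picked = coords[rng.choice(coords.shape[0], size=n, replace=False)]
    rows, cols = mask.mask.shape
    affected = set()
    for r, c in picked:
        r, c = int(r), int(c)
        affected.add((r, c))
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < rows and 0 <= cc < cols and mask.mask[rr, cc]:
                affected.add((rr, cc))
    return SeedSet(sorted(affected))


def grid_for_voxel(n_alveoli: int = 130) -> tuple[int, int]:
    """Most-square integer factorization rows x cols = n (130 -> 13 x 10)."""
    if n_alveoli < 1:
        raise ValueError("n_alveoli must be >= 1")
    best = (n_alveoli, 1)
    for a in range(int(np.sqrt(n_alveoli)), 0, -1):
        if n_alveoli % a == 0:
            best = (n_alveoli // a, a)
            break
    return best


def modulus_to_hu(E_mean: float, E0: float = E0_HEALTHY,
                  hu_orig: float = -820.0) -> float:
    """Linear translation of mean tissue stiffness back into HU.

    The healthy modulus ``E0`` maps to the original pixel value and a
    vanishing modulus to air (-1000 HU); intermediate values interpolate
    linearly.  The result is clipped to [-1000, hu_orig].
    """
    if E_mean <= 0:
        raise ValueError("E_mean must be > 0")
    if E_mean > E0:
        warnings.warn("E_mean above healthy reference; clipping to original HU",
                      stacklevel=2)
        return float(hu_orig)
    hu = HU_AIR + (hu_orig - HU_AIR) * (E_mean / E0)
    return float(np.clip(hu, HU_AIR, hu_orig))


def mld(patch: CTPatch, mask: ParenchymaMask) -> float:
    """Mean Lung Density: arithmetic mean HU over the parenchyma mask."""
    if mask.n_pixels == 0:
        raise ValueError("empty parenchyma mask")
    return float(patch.hu[mask.mask].mean())


def synth_patch(
    severity: str = "healthy",
    size: int = 61,
    seed: int = 0,
    base_mean: float = -820.0,
    base_sd: float = 40.0,
    n_vessels: int = 4,
    cluster_hu: float = -960.0,
) -> CTPatch:
    """Seeded synthetic CT patch emulating the three emphysema classes.

    Healthy parenchyma is Gaussian-textured around ``base_mean`` with sparse
    bright vessel streaks (above -500 HU).  The moderate and severe classes
    additionally carve 5 and 15 disk-shaped low-attenuation clusters (radii
    2-4 and 3-8 px) toward ``cluster_hu``, mimicking the growing holes of
    progressing emphysema.  This generator is a synthetic stand-in for real
    CT data; its defaults are package choices, not measured values.
    """
    if severity not in ("healthy", "moderate", "severe"):
        raise ValueError(f"severity must be healthy/moderate/severe, got {severity!r}")
    rng = np.random.default_rng(seed)
    hu = rng.normal(base_mean, base_sd, size=(size, size))

    # bright vessel streaks: short thick line segments well above -500 HU
    for _ in range(n_vessels):
        r0, c0 = rng.integers(0, size, 2)
        angle = rng.uniform(0, np.pi)
        length = rng.integers(5, max(6, size // 4))
        for t in range(int(length)):
            r = int(r0 + t * np.sin(angle))
            c = int(c0 + t * np.cos(angle))
            if 0 <= r < size and 0 <= c < size:
                hu[r, c] = rng.normal(-150.0, 80.0)

    if severity in ("moderate", "severe"):
        n_clusters, rad_lo, rad_hi = (5, 2, 4) if severity == "moderate" else (15, 3, 8)
        jj, ii = np.meshgrid(np.arange(size), np.arange(size))
        for _ in range(n_clusters):
            r0, c0 = rng.integers(0, size, 2)
            rad = rng.integers(rad_lo, rad_hi + 1)
            disk = (ii - r0) ** 2 + (jj - c0) ** 2 <= rad ** 2
            hu[disk] = rng.normal(cluster_hu, 12.0, size=int(disk.sum()))

    hu = np.clip(hu, HU_MIN, HU_MAX)
    return CTPatch(hu, severity=severity)


def group_compare(mlds_a, mlds_b) -> tuple[float, float]:
    """Welch two-sample t-test on two lists of MLD scores.

    Returns ``(mean(a) - mean(b), p_value)``.  With degenerate (zero)
    variance in both groups the p-value is 1.0 for identical means and 0.0
    otherwise.
    """
    a = np.asarray(mlds_a, dtype=float)
    b = np.asarray(mlds_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    if a.std() == 0 and b.std() == 0:
        warnings.warn("degenerate zero-variance groups", stacklevel=2)
        return diff, (1.0 if diff == 0 else 0.0)
    t = stats.ttest_ind(a, b, equal_var=False)
    return diff, float(t.pvalue)


def simulate_progression(
    patch: CTPatch,
    signal: SmokingSignal | None = None,
    n_seeds: int = 200,
    seed: int = 0,
    params: ImmuneParams | None = None,
    coupling: CouplingConfig | None = None,
    load: BreathingLoad | None = None,
) -> tuple[CTPatch, SeedSet]:
    """Run the per-voxel coupled model over a patch and remap HU.

    Random parenchyma pixels (plus 4-neighbors) are marked affected; each
    affected pixel runs one coupled agent/finite-element job on a planar
    grid of the ~130 alveoli contained in a CT voxel.  The job's final mean
    element modulus drives the linear HU remap of that pixel; unaffected
    pixels are unchanged.  Returns the progressed patch and the seed set.
    """
    signal = signal or SmokingSignal(e_s=10, T_s=50)
    params = params or ImmuneParams()
    coupling = coupling or CouplingConfig()
    load = load or BreathingLoad()

    mask = segment_parenchyma(patch)
    master = np.random.default_rng(seed)
    seeds = select_seeds(mask, n=n_seeds, seed=master)
    rows, cols = grid_for_voxel(
        alveoli_per_voxel(patch.spacing, patch.thickness))

    out = patch.copy()
    n_cycles = max(1, -(-signal.total_steps // coupling.ab_steps_per_cycle))
    coupling_job = CouplingConfig(
        ab_steps_per_cycle=coupling.ab_steps_per_cycle,
        damage_stop_fraction=coupling.damage_stop_fraction,
        max_cycles=n_cycles, nu=coupling.nu)
    for r, c in seeds.pixels:
        job_seed = int(master.integers(0, 2**31 - 1))
        cfg = ABConfig(rows=rows, cols=cols, seed=job_seed)
        ab = init_grid(cfg)
        ab, _ = run_coupled(ab, signal, params, cfg, coupling_job, load)
        e_mean = float(mixture_modulus(ab.cel, ab.ccl, ab.alive).mean())
        out.hu[r, c] = modulus_to_hu(min(e_mean, E0_HEALTHY),
                                     E0_HEALTHY, patch.hu[r, c])
    return out, seeds


def load_patch(
    path,
    hu_offset: float = 0.0,
    spacing: tuple[float, float] = (0.78, 0.78),
    thickness: float = 1.25,
    severity: str = "none",
) -> CTPatch:
    """Read a 2D patch from CSV, TIFF or PNG.

    Raw pixel values are shifted by ``hu_offset`` (stored pixel + offset =
    HU), the usual convention for unsigned image containers.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        arr = np.loadtxt(path, delimiter=",")
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path), dtype=float)
    elif suffix == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=float)
    else:
        raise ValueError(f"unsupported patch format {suffix!r}")
    return CTPatch(arr + hu_offset, spacing=spacing, thickness=thickness,
                   severity=severity)
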