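"""Synthetic CT-like cohorts for end-to-end testing of the pipeline.

Real lesion cohorts (tens of thousands of annotated CT lesions, paired
retest scans, survival follow-up, RNA-seq profiles) cannot ship with a
package, so this module generates volumes that carry the statistical
structure the method relies on:

* lung-like background: mean -800 HU with spatially correlated noise;
* ellipsoidal lesions whose class identity is encoded in sinusoidal texture
  frequency and intensity offset, so a trained encoder can separate classes
  while a random one finds them noisy;
* survival times from an exponential model whose log-hazard is linear in
  lesion radius, supporting Cox / log-rank sanity checks in closed form;
* retest twins (small rigid shift + fresh acquisition noise) and a gene
  expression matrix in which a known subset of genes correlates with the
  lesion phenotype.

Every generator is a pure function of its parameters and the supplied
``numpy.random.Generator``; the same seed reproduces a cohort bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import HU_MIN, HU_MAX, LesionRecord, SeedPoint, VolumeGrid
from .volumes import seed_from_mask, write_volume

DAYS_2YR = 730.0

# Study conditions for the default three-class cohort.  Lesions are
# soft-tissue-density ellipsoids in lung-like parenchyma (contrast about
# 700-800 HU against a -800 HU background, as for real pulmonary lesions);
# class identity is carried chiefly by the spatial frequency of the internal
# texture, with a small density difference between classes.
# Class identity is carried jointly by the spatial frequency of a concentric
# ring texture and a modest density offset; alternative texture arrangements
# (parallel laminae, 3D lattice) are available through LesionSpec for harder
# phantoms.
DEFAULT_CLASS_PATTERNS = ("ring", "ring", "ring")
DEFAULT_CLASS_FREQS = (0.07, 0.18, 0.35)
DEFAULT_CLASS_OFFSETS = (720.0, 750.0, 780.0)
DEFAULT_TEXTURE_AMPLITUDE = 150.0
DEFAULT_EDGE_MM = 72


@dataclass(frozen=True)
class LesionSpec:
    """Geometric and textural description of one synthetic lesion.

    ``texture_pattern`` selects the spatial arrangement of the sinusoidal
    texture: ``ring`` (concentric shells), ``plane`` (parallel laminae along
    a random direction) or ``grid`` (a 3D lattice in a random frame).  All
    patterns are scaled to the same voxelwise variance.
    """

    class_id: int
    radius_mm: float
    texture_amplitude: float = DEFAULT_TEXTURE_AMPLITUDE
    texture_frequency: float = 0.25
    intensity_offset: float = 750.0
    texture_pattern: str = "ring"

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")
        if self.texture_frequency <= 0:
            raise ValueError("texture_frequency must be positive")
        if self.class_id < 0:
            raise ValueError("class_id must be non-negative")
        if self.texture_pattern not in ("ring", "plane", "grid"):
            raise ValueError(f"unknown texture pattern {self.texture_pattern!r}")


@dataclass(frozen=True)
class BackgroundParams:
    """Correlated-noise background: Gaussian noise smoothed with a fixed kernel."""

    mean_hu: float = -800.0
    sd_hu: float = 60.0
    smooth_mm: float = 2.0


@dataclass(frozen=True)
class RetestJitter:
    """Acquisition differences between two scans taken minutes apart."""

    shift_voxels: Tuple[float, float, float] = (0.4, 0.4, 0.4)  # SD of rigid shift per axis
    noise_sd_hu: float = 12.0


@dataclass
class SyntheticCohort:
    """A bundle of volumes, lesion annotations and optional side data."""

    volumes: List[VolumeGrid]
    lesions: List[LesionRecord]
    masks: List[np.ndarray] = field(default_factory=list)
    retest_pairs: Optional[List[Tuple[int, VolumeGrid]]] = None
    expression: Optional[pd.DataFrame] = None  # genes x cases
    generator_seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.lesions):
            raise ValueError("one LesionRecord per volume is required")

    def __len__(self) -> int:
        return len(self.volumes)

    def table(self) -> pd.DataFrame:
        rows = []
        for rec in self.lesions:
            x, y, z = rec.seed.xyz
            rows.append(
                {
                    "case_id": rec.scan_id,
                    "seed_x_mm": x,
                    "seed_y_mm": y,
                    "seed_z_mm": z,
                    "class": rec.site_class,
                    "event": rec.event,
                    "time_days": rec.time_days,
                    "label_2yr": rec.label_2yr,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir) -> Path:
        """Persist volumes/masks as NIfTI, the cohort table as CSV, expression as TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for vol, rec in zip(self.volumes, self.lesions):
            write_volume(vol, out / f"{rec.scan_id}.nii.gz")
        for mask, rec in zip(self.masks, self.lesions):
            write_volume(
                VolumeGrid(mask.astype(np.float32), spacing=self.volumes[0].spacing),
                out / f"{rec.scan_id}_mask.nii.gz",
            )
        self.table().to_csv(out / "cohort.csv", index=False)
        if self.expression is not None:
            self.expression.to_csv(out / "expression.tsv", sep="\t")
        return out


def _correlated_background(shape, params: BackgroundParams, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, size=shape)
    if params.smooth_mm > 0:
        noise = ndimage.gaussian_filter(noise, sigma=params.smooth_mm)
        sd = noise.std()
        if sd > 0:
            noise /= sd
    return params.mean_hu + params.sd_hu * noise


def make_volume(
    spec: LesionSpec,
    edge_mm: int = DEFAULT_EDGE_MM,
    background: BackgroundParams = BackgroundParams(),
    rng: Optional[np.random.Generator] = None,
    center_jitter_mm: float = 4.0,
    axis_ratio_range: Tuple[float, float] = (0.8, 1.0),
) -> Tuple[VolumeGrid, np.ndarray, SeedPoint]:
    """One 1 mm-isotropic volume containing a single ellipsoidal lesion.

    Returns the volume, the exact lesion voxel mask and the mask centroid as
    the seed point.  Raises if the lesion cannot fit with margin.
    """
    rng = np.random.default_rng(rng)
    if edge_mm < 2 * spec.radius_mm + 8:
        raise ValueError("lesion does not fit: need edge_mm >= 2*radius_mm + 8")
    shape = (edge_mm, edge_mm, edge_mm)
    vol = _correlated_background(shape, background, rng)

    center = np.full(3, edge_mm / 2.0) + rng.uniform(-center_jitter_mm, center_jitter_mm, size=3)
    radii = spec.radius_mm * rng.uniform(*axis_ratio_range, size=3)
    radii[rng.integers(0, 3)] = spec.radius_mm  # keep the nominal radius on one axis
    coords = np.indices(shape, dtype=float)
    d2 = sum(((coords[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    mask = d2 <= 1.0

    rel = [coords[a] - center[a] for a in range(3)]
    f = spec.texture_frequency
    if spec.texture_pattern == "ring":
        r_mm = np.sqrt(sum(c ** 2 for c in rel))
        texture = spec.texture_amplitude * np.cos(2 * np.pi * f * r_mm)
    elif spec.texture_pattern == "plane":
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        texture = spec.texture_amplitude * np.cos(2 * np.pi * f * sum(u[a] * rel[a] for a in range(3)))
    else:  # grid: separable lattice in a random frame, per-axis frequency
        # f/sqrt(3) so the dominant wavevector magnitude matches the others,
        # and amplitude x2 so the voxelwise variance matches (A^2/2)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        g = f / np.sqrt(3.0)
        rot = [sum(q[a, b] * rel[b] for b in range(3)) for a in range(3)]
        texture = (2.0 * spec.texture_amplitude
                   * np.cos(2 * np.pi * g * rot[0])
                   * np.cos(2 * np.pi * g * rot[1])
                   * np.cos(2 * np.pi * g * rot[2]))
    vol = np.where(mask, background.mean_hu + spec.intensity_offset + texture, vol)
    if background.sd_hu > 0:
        # lesion voxels get the same acquisition-noise level as the background
        vol = np.where(mask, vol + rng.normal(0.0, background.sd_hu * 0.25, size=shape), vol)
    vol = np.clip(vol, HU_MIN, HU_MAX).astype(np.float32)
    grid = VolumeGrid(vol, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))
    seed = seed_from_mask(mask, spacing=grid.spacing, origin=grid.origin)
    return grid, mask, seed


def _balanced_labels(n: int, K: int, rng: np.random.Generator) -> np.ndarray:
    base = np.concatenate([np.full(n // K + (1 if i < n % K else 0), i) for i in range(K)])
    return rng.permutation(base)


def make_classification_cohort(
    n: int,
    K: int = 3,
    rng: Optional[np.random.Generator] = None,
    edge_mm: int = DEFAULT_EDGE_MM,
    radius_range: Tuple[float, float] = (5.0, 9.0),
    class_patterns: Sequence[str] = DEFAULT_CLASS_PATTERNS,
    class_freqs: Sequence[float] = DEFAULT_CLASS_FREQS,
    class_offsets: Sequence[float] = DEFAULT_CLASS_OFFSETS,
    offset_jitter: float = 0.0,
    background: BackgroundParams = BackgroundParams(),
) -> SyntheticCohort:
    """A label-balanced K-class lesion cohort (site-classification analogue).

    Classes differ in texture frequency and density offset under the default
    palette (arrangement is also configurable); ``offset_jitter`` adds
    uniform per-case density noise to soften the density cue if desired.
    """
    rng = np.random.default_rng(rng)
    if K < 2:
        raise ValueError("need at least two classes")
    if n < K:
        raise ValueError("need n >= K")
    if K > len(class_patterns):
        raise ValueError(f"default class palette supports K <= {len(class_patterns)}")
    labels = _balanced_labels(n, K, rng)
    volumes, lesions, masks = [], [], []
    for i, k in enumerate(labels):
        spec = LesionSpec(
            class_id=int(k),
            radius_mm=float(rng.uniform(*radius_range)),
            texture_pattern=class_patterns[k],
            texture_frequency=float(class_freqs[k]),
            intensity_offset=float(class_offsets[k] + rng.uniform(-offset_jitter, offset_jitter)),
        )
        vol, mask, seed = make_volume(spec, edge_mm=edge_mm, background=background, rng=rng)
        volumes.append(vol)
        masks.append(mask)
        lesions.append(LesionRecord(scan_id=f"case_{i:04d}", seed=seed, site_class=int(k)))
    return SyntheticCohort(volumes=volumes, lesions=lesions, masks=masks)


def make_survival_cohort(
    n: int,
    hazard_link: float = 0.25,
    censor_rate: float = 0.25,
    rng: Optional[np.random.Generator] = None,
    edge_mm: int = DEFAULT_EDGE_MM,
    radius_range: Tuple[float, float] = (4.0, 10.0),
    median_time_days: float = 540.0,
    background: BackgroundParams = BackgroundParams(),
    make_volumes: bool = True,
) -> SyntheticCohort:
    """Survival cohort with exponential event times, log-hazard linear in radius.

    ``hazard_link`` is the log-hazard coefficient per mm of lesion radius
    (centred at the mid-range radius); larger lesions die sooner when it is
    positive.  Censoring is uniform-independent, calibrated to the requested
    rate; the 2-year binary label is right-censored: cases censored before
    730 days get ``label_2yr = None``.
    """
    rng = np.random.default_rng(rng)
    if n < 20:
        raise ValueError("survival cohort needs n >= 20")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    radii = rng.uniform(*radius_range, size=n)
    r0 = np.mean(radius_range)
    lam0 = np.log(2.0) / median_time_days
    lam = lam0 * np.exp(hazard_link * (radii - r0))
    true_times = rng.exponential(1.0 / lam)

    if censor_rate > 0:
        # uniform censoring on [0, c_max]; calibrate c_max by bisection so the
        # expected censored fraction matches censor_rate
        def frac_censored(c_max: float) -> float:
            t = np.linspace(1e-6, c_max, 512)
            # P(C < T) with C ~ U(0, c_max): mean over cases of E[S(C)]
            surv = np.exp(-np.outer(lam, t))
            return float(np.mean(surv.mean(axis=1)))

        lo, hi = 1.0, 50 * median_time_days
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if frac_censored(mid) > censor_rate:
                lo = mid
            else:
                hi = mid
        censor_times = rng.uniform(0.0, 0.5 * (lo + hi), size=n)
    else:
        censor_times = np.full(n, np.inf)

    events = (true_times <= censor_times).astype(int)
    obs_times = np.minimum(true_times, censor_times)

    volumes, lesions, masks = [], [], []
    for i in range(n):
        t = float(obs_times[i])
        e = int(events[i])
        if t >= DAYS_2YR:
            label_2yr = 1  # alive at 2 years (event or censoring happened later)
        elif e == 1:
            label_2yr = 0  # death observed before 2 years
        else:
            label_2yr = None  # censored before 2 years: endpoint unknown
        if make_volumes:
            spec = LesionSpec(class_id=0, radius_mm=float(radii[i]),
                              texture_frequency=DEFAULT_CLASS_FREQS[1],
                              intensity_offset=DEFAULT_CLASS_OFFSETS[1])
            vol, mask, seed = make_volume(spec, edge_mm=edge_mm, background=background, rng=rng)
            volumes.append(vol)
            masks.append(mask)
        else:
            seed = SeedPoint((edge_mm / 2.0,) * 3)
        lesions.append(
            LesionRecord(
                scan_id=f"surv_{i:04d}",
                seed=seed,
                event=e,
                time_days=t,
                label_2yr=label_2yr,
            )
        )
    if not make_volumes:
        # keep the one-record-per-volume invariant with empty placeholder grids
        volumes = [VolumeGrid(np.full((2, 2, 2), -800.0, dtype=np.float32)) for _ in range(n)]
        masks = [np.zeros((2, 2, 2), dtype=bool) for _ in range(n)]
    return SyntheticCohort(volumes=volumes, lesions=lesions, masks=masks)


def make_retest_pair(
    volume: VolumeGrid,
    jitter: RetestJitter = RetestJitter(),
    rng: Optional[np.random.Generator] = None,
) -> VolumeGrid:
    """A retest twin: the volume under a small rigid shift plus fresh noise."""
    rng = np.random.default_rng(rng)
    shift = rng.normal(0.0, np.asarray(jitter.shift_voxels, dtype=float))
    out = volume.intensities.astype(np.float64)
    if np.any(np.abs(shift) > 0):
        out = ndimage.shift(out, shift=shift, order=1, mode="nearest")
    if jitter.noise_sd_hu > 0:
        out = out + rng.normal(0.0, jitter.noise_sd_hu, size=out.shape)
    out = np.clip(out, HU_MIN, HU_MAX).astype(np.float32)
    return VolumeGrid(out, spacing=volume.spacing, origin=volume.origin)


def make_expression(
    phenotype: np.ndarray,
    G: int = 1000,
    g_informative: int = 50,
    r_target: float = 0.6,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Gene-expression matrix (genes x cases) with a known informative subset.

    Informative genes have population correlation ``r_target`` with the
    phenotype; the rest are independent noise.  Per-gene means and scales are
    heterogeneous (lognormal scales, wide means) so the mean/SD filter used
    in the screening step is non-trivial.  Returns the matrix and the list of
    informative gene ids.
    """
    rng = np.random.default_rng(rng)
    phenotype = np.asarray(phenotype, dtype=float)
    n = phenotype.size
    if g_informative > G:
        raise ValueError("g_informative must not exceed G")
    if abs(r_target) >= 1:
        raise ValueError("|r_target| must be < 1")
    z = (phenotype - phenotype.mean()) / (phenotype.std() + 1e-12)
    gene_ids = [f"GENE{g:05d}" for g in range(G)]
    informative = sorted(rng.choice(G, size=g_informative, replace=False).tolist())
    data = np.empty((G, n))
    means = rng.normal(8.0, 3.0, size=G)
    scales = rng.lognormal(0.0, 0.6, size=G)
    info_set = set(informative)
    for g in range(G):
        noise = rng.normal(0.0, 1.0, size=n)
        if g in info_set:
            latent = r_target * z + np.sqrt(1.0 - r_target**2) * noise
        else:
            latent = noise
        data[g] = means[g] + scales[g] * latent
    expr = pd.DataFrame(data, index=gene_ids, columns=[f"case_{i:04d}" for i in range(n)])
    return expr, [gene_ids[g] for g in informative]
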