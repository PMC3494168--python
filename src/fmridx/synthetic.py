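"""Synthetic multi-site resting-state cohorts with known class structure.

Real multi-site ADHD cohorts cannot be redistributed, so every downstream
stage is exercised on generated data whose ground truth is known exactly.
A cohort consists of one 4-D scan per subject plus a phenotypic table
(age, gender, handedness, three IQ scores, site, diagnosis).

The generator emulates the study conditions the pipeline was designed for:

* multiple acquisition sites with site-dependent volume times (the real
  cohort used 1.5, 1.96, 2.0, 2.5 and 3.0 s);
* a fixed "brain" region of positive mean intensity surrounded by
  out-of-brain voxels of negative mean intensity (so the sign-of-mean mask
  rule recovers the brain), with an optional per-site gain factor emulating
  scanner-configuration magnitude differences;
* class-dependent low-frequency sinusoidal signatures (within the
  0.001-0.1 Hz resting-state band) added to a designated sub-region of
  in-brain voxels, with a random phase per subject so the diagnostic
  information lives in the frequency *magnitudes*, not the raw waveforms;
* i.i.d. Gaussian voxel noise.

The default grid is a desk-scale 12 x 12 x 10 with two sites; the full
57 x 67 x 50 grid is supported but not the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .preprocess import Scan4D

#: Diagnostic classes, in generation order.
CLASSES = ("control", "combined", "inattentive")

#: Phenotypic CSV column order.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "age",
    "gender",
    "handedness",
    "viq",
    "piq",
    "fiq",
    "site",
    "dx",
)

#: Per-site subject counts of the 668-subject training cohort
#: (site, n, control, combined, inattentive).  The NeuroIMAGE row is
#: reconstructed from the printed class totals (429/141/98); see
#: docs/methods.md.
ADHD200_TRAIN_SITES = (
    ("KKI", 78, 58, 15, 5),
    ("NeuroIMAGE", 38, 22, 16, 0),
    ("Peking", 194, 116, 29, 49),
    ("OHSU", 64, 36, 17, 11),
    ("NYU", 188, 91, 64, 33),
    ("Pittsburgh", 66, 66, 0, 0),
    ("WashU", 40, 40, 0, 0),
)

#: Per-site subject counts of the 171-subject holdout cohort.
ADHD200_HOLDOUT_SITES = (
    ("KKI", 11, 8, 3, 0),
    ("NeuroIMAGE", 25, 14, 11, 0),
    ("Peking", 51, 27, 10, 14),
    ("OHSU", 34, 28, 5, 1),
    ("NYU", 41, 12, 22, 7),
    ("Pittsburgh", 9, 5, 0, 4),
    ("WashU", 0, 0, 0, 0),
)

#: Volume times (s) used across the real acquisition sites.
SITE_VOLUME_TIMES = (1.5, 1.96, 2.0, 2.5, 3.0)


@dataclass(frozen=True)
class SiteSpec:
    """One acquisition site: name, volume time and per-class subject counts."""

    name: str
    volume_time_s: float
    n_control: int
    n_combined: int
    n_inattentive: int

    @property
    def counts(self) -> dict[str, int]:
        return {
            "control": self.n_control,
            "combined": self.n_combined,
            "inattentive": self.n_inattentive,
        }

    @property
    def n_subjects(self) -> int:
        return self.n_control + self.n_combined + self.n_inattentive


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    ``signal_region`` is a set of raw-grid ``(x, y, z)`` coordinates whose
    waveforms carry the class signature sinusoids; ``signatures`` maps each
    class to a list of ``(frequency_hz, amplitude)`` pairs.  ``brain_region``
    is the designed in-brain set (baseline ``baseline_in`` inside, negative
    ``baseline_out`` outside); by default a centered box aligned to whole
    ``avg k=3`` blocks so the recovered mask is unambiguous.
    """

    sites: Sequence[SiteSpec]
    grid: tuple[int, int, int] = (12, 12, 10)
    duration_s: float = 185.0
    signal_region: Optional[frozenset] = None  # None -> central brain block
    signatures: dict = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline_in: float = 10.0
    baseline_out: float = -10.0
    brain_region: Optional[frozenset] = None
    site_gain: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.brain_region is None:
            self.brain_region = default_brain_region(self.grid)
        self.brain_region = frozenset(tuple(c) for c in self.brain_region)
        if self.signal_region is None:
            self.signal_region = central_signal_region(self.brain_region, self.grid)
        self.signal_region = frozenset(tuple(c) for c in self.signal_region)
        self.validate()

    def validate(self) -> None:
        if not self.sites:
            raise ValidationError("sites: at least one site is required")
        for s in self.sites:
            if min(s.n_control, s.n_combined, s.n_inattentive) < 0:
                raise ValidationError(f"sites: negative class count at site {s.name!r}")
            if not s.volume_time_s > 0:
                raise ValidationError(f"sites: non-positive volume time at site {s.name!r}")
        if len(self.grid) != 3 or min(self.grid) < 1:
            raise ValidationError("grid: must be three positive voxel counts")
        if self.duration_s < 185.0:
            raise ValidationError("duration_s: must be >= 185 s, the common truncation length")
        nyquist = min(0.5 / s.volume_time_s for s in self.sites)
        for cls, sigs in self.signatures.items():
            if cls not in CLASSES:
                raise ValidationError(f"signatures: unknown class {cls!r}")
            for f, a in sigs:
                if not 0 < f < nyquist:
                    raise ValidationError(
                        f"signatures: frequency {f} Hz is not below the slowest "
                        f"site's Nyquist rate {nyquist:.4f} Hz"
                    )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd: must be nonnegative")
        if not self.baseline_in > 0:
            raise ValidationError("baseline_offset_in_brain: must be positive")
        if not self.baseline_out < 0:
            raise ValidationError("baseline_offset_out_of_brain: must be negative")
        for coord in self.signal_region:
            if coord not in self.brain_region:
                raise ValidationError(f"signal_region: {coord} lies outside the brain region")
        for x, y, z in self.brain_region:
            if not (0 <= x < self.grid[0] and 0 <= y < self.grid[1] and 0 <= z < self.grid[2]):
                raise ValidationError(f"brain_region: {(x, y, z)} lies outside the grid")

    @property
    def n_subjects(self) -> int:
        return sum(s.n_subjects for s in self.sites)


@dataclass
class GroundTruth:
    """What the generator actually planted: labels, regions, signatures."""

    labels: list[str]
    sites: list[str]
    signal_region: frozenset
    signatures: dict
    brain_region: frozenset


def default_brain_region(grid: tuple[int, int, int]) -> frozenset:
    """Centered box occupying the middle ~half of each axis, aligned to
    k=3 blocks where the grid allows, so block averaging keeps the
    in/out-of-brain boundary sharp."""
    lo_hi = []
    for n in grid:
        lo = 3 * max(1, round(n / 3 / 4))
        hi = min(n, 3 * max(2, round(2 * n / 3 / 3)))
        lo_hi.append((min(lo, n - 1), max(hi, min(lo + 1, n))))
    (x0, x1), (y0, y1), (z0, z1) = lo_hi
    return frozenset(
        (x, y, z)
        for x in range(x0, x1)
        for y in range(y0, y1)
        for z in range(z0, z1)
    )


def _region_mask(region: frozenset, grid: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(grid, dtype=bool)
    for x, y, z in region:
        m[x, y, z] = True
    return m


#: Default class signatures: one low-frequency component per class, each an
#: exact multiple of the 1/185 Hz resolution of the standardized window so
#: the planted power lands in a single DFT bin.
DEFAULT_SIGNATURES = {
    "control": [(4 / 185.0, 2.0)],
    "combined": [(9 / 185.0, 2.0)],
    "inattentive": [(15 / 185.0, 2.0)],
}


def default_cohort_spec(
    n_control: int = 16,
    n_combined: int = 8,
    n_inattentive: int = 6,
    noise_sd: float = 1.0,
    seed: int = 0,
    grid: tuple[int, int, int] = (12, 12, 10),
    duration_s: float = 185.0,
    site_gain: Optional[dict] = None,
) -> CohortSpec:
    """Two-site desk-scale cohort with the default class signatures.

    Subjects are split across two sites with volume times 2.0 s and 2.5 s
    (the two most common in multi-site resting-state acquisitions); class
    counts are divided as evenly as possible, remainder to the first site.
    The signal region is the central k=3 block of the brain region.
    """
    halves = [(n + 1) // 2 for n in (n_control, n_combined, n_inattentive)]
    site_a = SiteSpec("site_a", 2.0, *halves)
    site_b = SiteSpec(
        "site_b", 2.5, n_control - halves[0], n_combined - halves[1], n_inattentive - halves[2]
    )
    brain = default_brain_region(grid)
    signal = central_signal_region(brain, grid)
    return CohortSpec(
        sites=(site_a, site_b),
        grid=grid,
        duration_s=duration_s,
        signal_region=signal,
        signatures={c: list(v) for c, v in DEFAULT_SIGNATURES.items()},
        noise_sd=noise_sd,
        site_gain=dict(site_gain or {}),
        seed=seed,
    )


def central_signal_region(brain_region: frozenset, grid: tuple[int, int, int]) -> frozenset:
    """The k=3 block of the brain region closest to the grid center."""
    coords = np.array(sorted(brain_region))
    center = coords.mean(axis=0)
    block = (np.floor(center / 3).astype(int)) * 3
    region = frozenset(
        (x, y, z)
        for x in range(block[0], block[0] + 3)
        for y in range(block[1], block[1] + 3)
        for z in range(block[2], block[2] + 3)
        if (x, y, z) in brain_region
    )
    if not region:  # tiny grids: fall back to the single nearest voxel
        idx = int(np.argmin(((coords - center) ** 2).sum(axis=1)))
        region = frozenset({tuple(coords[idx])})
    return region


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Scan4D], pd.DataFrame, GroundTruth]:
    """Generate one scan per subject plus phenotypes and ground truth.

    Subjects are ordered site by site and, within a site, class by class in
    the order control, combined, inattentive.  Scans sample times
    ``0, TR, ..., ceil(duration/TR)*TR`` so the sampled span always covers
    the stated duration at every site's volume time.  Bit-identical outputs
    are produced for identical (spec, seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L, W, H = spec.grid
    brain = _region_mask(spec.brain_region, spec.grid)
    signal = _region_mask(spec.signal_region, spec.grid)
    baseline = np.where(brain, spec.baseline_in, spec.baseline_out)

    scans: list[Scan4D] = []
    labels: list[str] = []
    sites: list[str] = []
    for site in spec.sites:
        tr = site.volume_time_s
        n_t = int(math.ceil(spec.duration_s / tr)) + 1
        t = np.arange(n_t) * tr
        gain = float(spec.site_gain.get(site.name, 1.0))
        for cls in CLASSES:
            for _ in range(site.counts[cls]):
                values = np.broadcast_to(
                    baseline[..., None], (L, W, H, n_t)
                ).astype(float).copy()
                wave = np.zeros(n_t)
                for f, a in spec.signatures.get(cls, ()):
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    wave += a * np.sin(2.0 * np.pi * f * t + phase)
                values[signal] += wave
                if spec.noise_sd > 0:
                    values += rng.normal(0.0, spec.noise_sd, size=values.shape)
                scans.append(
                    Scan4D(values=values * gain, sampling_period=tr, voxel_size=(3.0, 3.0, 3.0))
                )
                labels.append(cls)
                sites.append(site.name)

    phenotypes = generate_phenotypes(labels, sites, seed=int(rng.integers(2**31)))
    truth = GroundTruth(
        labels=labels,
        sites=sites,
        signal_region=spec.signal_region,
        signatures={c: list(v) for c, v in spec.signatures.items()},
        brain_region=spec.brain_region,
    )
    return scans, phenotypes, truth


def generate_phenotypes(
    labels: Sequence[str],
    sites: Sequence[str],
    seed: int = 0,
    missing_fraction: float = 0.1,
    iq_shift: Optional[dict] = None,
) -> pd.DataFrame:
    """Phenotypic table: age, gender, handedness, three IQ scores, site, dx.

    Ages are drawn to mimic a mostly-adolescent cohort; IQ scores are
    N(110, 14) with a configurable fraction missing at random.  ``iq_shift``
    optionally adds a class-conditional offset to the Full IQ column,
    making the phenotypes informative about diagnosis.
    """
    if len(labels) != len(sites):
        raise ValidationError("labels and sites must pair one per subject")
    if not 0.0 <= missing_fraction <= 1.0:
        raise ValidationError("missing_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = len(labels)
    age = np.clip(rng.normal(13.0, 3.0, n), 7.0, 26.0).round(2)
    gender = rng.choice(["F", "M"], n)
    handedness = rng.choice(["R", "L"], n, p=[0.9, 0.1])
    iq = {c: rng.normal(110.0, 14.0, n).round(1) for c in ("viq", "piq", "fiq")}
    if iq_shift:
        shift = np.array([float(iq_shift.get(lbl, 0.0)) for lbl in labels])
        iq["fiq"] = iq["fiq"] + shift
    for c in iq:
        miss = rng.random(n) < missing_fraction
        iq[c] = np.where(miss, np.nan, iq[c])
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "age": age,
            "gender": gender,
            "handedness": handedness,
            "viq": iq["viq"],
            "piq": iq["piq"],
            "fiq": iq["fiq"],
            "site": list(sites),
            "dx": list(labels),
        }
    )


def adhd200_like_labels(table: Sequence[tuple] = ADHD200_TRAIN_SITES) -> tuple[list[str], list[str]]:
    """Expand a per-site count table into per-subject (labels, sites)."""
    labels: list[str] = []
    sites: list[str] = []
    for name, n, n_ctrl, n_comb, n_inatt in table:
        if n_ctrl + n_comb + n_inatt != n:
            raise ValidationError(f"site {name!r}: class counts do not sum to {n}")
        for cls, cnt in zip(CLASSES, (n_ctrl, n_comb, n_inatt)):
            labels.extend([cls] * cnt)
            sites.extend([name] * cnt)
    return labels, sites


def separable_cohort_spec(seed: int = 0) -> CohortSpec:
    """The noise-free 60-subject recovery benchmark: two sites, distinct
    class signatures, 32 control / 16 combined / 12 inattentive."""
    return default_cohort_spec(
        n_control=32, n_combined=16, n_inattentive=12, noise_sd=0.0, seed=seed
    )


# ---------------------------------------------------------------------------
# Disk formats (NIfTI-1 scans, CSV phenotypes)
# ---------------------------------------------------------------------------

def write_cohort(
    directory, scans: Sequence[Scan4D], phenotypes: pd.DataFrame
) -> list[Path]:
    """Write scans as ``<subject_id>.nii.gz`` plus ``phenotypes.csv``.

    Missing IQ values are encoded as empty fields.  Returns written paths.
    """
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if len(scans) != len(phenotypes):
        raise ValidationError("one scan per phenotype row is required")
    paths = []
    for scan, sid in zip(scans, phenotypes["subject_id"]):
        affine = np.diag(list(scan.voxel_size) + [1.0])
        img = nib.Nifti1Image(scan.values.astype(np.float32), affine)
        img.header.set_zooms(tuple(scan.voxel_size) + (scan.sampling_period,))
        img.header.set_xyzt_units("mm", "sec")
        path = directory / f"{sid}.nii.gz"
        nib.save(img, path)
        paths.append(path)
    csv_path = directory / "phenotypes.csv"
    phenotypes.to_csv(csv_path, index=False, columns=list(PHENOTYPE_COLUMNS))
    paths.append(csv_path)
    return paths
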