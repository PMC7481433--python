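"""Synthetic graded prostate-MRI phantoms.

Real T2-weighted fat-suppressed stacks used for grade-group work are not
publicly deposited, so this module generates volumetric phantoms with the
statistical structure the rest of the package assumes: stacks of 18-24
axial slices, a contiguous run of 8-12 slices containing the gland, and a
contiguous sub-run of 4-10 tumor-bearing slices whose intensity and texture
encode the patient-level grade group (1-5).

Each phantom also carries a simulated needle-biopsy grade (``gg_nb``)
produced by a confusion kernel calibrated so that, marginally, biopsy
under-calls the prostatectomy grade about 40% of the time and over-calls it
about 15% of the time — the discordance pattern reported for systematic
biopsy cohorts.

The lesion signature is a mean-intensity shift plus a sinusoidal (Gabor-like)
texture whose frequency grows with grade; both are scaled by
``signal_separation``, so separation 0 yields lesions indistinguishable from
gland tissue and larger values make grades progressively easier to tell
apart.  A mild through-plane intensity ramp emulates coil-sensitivity /
anatomy variation along the stack axis, which gives slice appearance a weak
dependence on axial position.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "VolumeStack",
    "generate_patient",
    "generate_cohort",
    "write_fixture",
    "read_fixture",
    "TABLE_GRADE_COUNTS",
]

# Pooled five-grade prostatectomy marginal used as the default class prior
# (counts per grade group 1..5 over a 575-patient two-hospital cohort).
TABLE_GRADE_COUNTS = (82, 152, 117, 85, 139)

# gg_nb = gg_rp + offset, offset in {-2,-1,0,+1,+2}; negative offsets are
# biopsy under-calls (upgrading at prostatectomy).  Mass below the diagonal
# is 0.40, above 0.15, matching reported systematic-biopsy discordance.
DEFAULT_NB_KERNEL = {-2: 0.12, -1: 0.28, 0: 0.45, 1: 0.12, 2: 0.03}


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a phantom cohort.

    Ranges are inclusive ``(low, high)`` tuples; each patient draws its own
    counts uniformly from them.
    """

    n_patients: int = 60
    slices_per_patient: tuple[int, int] = (18, 24)
    gland_slices: tuple[int, int] = (8, 12)
    lesion_slices: tuple[int, int] = (4, 10)
    grade_probs: tuple[float, ...] = tuple(
        c / sum(TABLE_GRADE_COUNTS) for c in TABLE_GRADE_COUNTS)
    image_size: int = 256
    signal_separation: float = 1.0
    noise_sd: float = 0.03
    nb_kernel: dict = field(default_factory=lambda: dict(DEFAULT_NB_KERNEL))
    second_lesion_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if len(self.grade_probs) != 5:
            raise ValueError("grade_probs must have 5 entries")
        if abs(sum(self.grade_probs) - 1.0) > 1e-9:
            raise ValueError("grade_probs must sum to 1 within 1e-9")
        if min(self.grade_probs) < 0:
            raise ValueError("grade_probs must be nonnegative")
        for name in ("slices_per_patient", "gland_slices", "lesion_slices"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if not (self.lesion_slices[0] >= 1
                and self.lesion_slices[1] <= self.gland_slices[1]):
            raise ValueError("lesion_slices range must fit inside gland_slices")
        if self.gland_slices[1] > self.slices_per_patient[0]:
            raise ValueError("gland run must fit in the shortest stack")
        if self.image_size < 200:
            raise ValueError("image_size must be >= 200 (crop window)")
        if abs(sum(self.nb_kernel.values()) - 1.0) > 1e-9:
            raise ValueError("nb_kernel probabilities must sum to 1")
        if self.noise_sd < 0 or self.signal_separation < 0:
            raise ValueError("noise_sd and signal_separation must be >= 0")

    def config_hash(self) -> str:
        payload = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.__dict__.items()}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class VolumeStack:
    """One patient's image stack: the RL environment.

    ``slices`` is ``(n_slices, H, W)`` float32, ordered inferior-to-superior
    with 0-based indices.  ``tumor_flags`` marks the slices carrying lesion
    signal; flags of a lesion form one contiguous run per lesion.
    """

    patient_id: str
    slices: np.ndarray
    tumor_flags: np.ndarray
    gg_rp: int | None = None
    gg_nb: int | None = None
    lesion_masks: dict[int, np.ndarray] | None = None
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 3.0)
    slice_order: str = "inferior-to-superior"

    def __post_init__(self):
        self.slices = np.asarray(self.slices, dtype=np.float32)
        self.tumor_flags = np.asarray(self.tumor_flags, dtype=bool)
        if self.slices.ndim != 3:
            raise ValueError("slices must be a (n, H, W) array")
        if len(self.tumor_flags) != len(self.slices):
            raise ValueError("one tumor flag per slice required")
        for g in (self.gg_rp, self.gg_nb):
            if g is not None and g not in range(1, 6):
                raise ValueError(f"grade label must be in 1..5, got {g}")
        if self.gg_rp is not None and not self.tumor_flags.any():
            raise ValueError("a graded stack must contain >= 1 tumor slice")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def median_index(self) -> int:
        """Start slice for inference: lower median, 0-based."""
        return self.n_slices // 2


def _sample_nb_grade(grade: int, kernel: dict, rng: np.random.Generator) -> int:
    offsets = sorted(kernel)
    probs = np.array([kernel[o] for o in offsets])
    off = rng.choice(offsets, p=probs / probs.sum())
    return int(np.clip(grade + off, 1, 5))


def _paint_lesion(img: np.ndarray, mask: np.ndarray, grade: int,
                  separation: float, xx: np.ndarray, yy: np.ndarray,
                  taper: float = 1.0) -> None:
    """Additive lesion signal: intensity shift + grade-keyed texture.

    Both cues scale linearly with ``separation`` so that separation 0
    leaves the lesion statistically identical to gland tissue.
    """
    freq = 0.05 + 0.03 * grade          # cycles / pixel
    texture = np.sin(2 * np.pi * freq * xx) * np.sin(2 * np.pi * freq * yy)
    img[mask] += taper * separation * (0.06 * grade
                                       + 0.05 * texture[mask])


def _place_run(total: int, length: int, center_jitter: int,
               rng: np.random.Generator, lo: int = 0,
               hi: int | None = None) -> int:
    """Start index of a contiguous run, centered with bounded jitter."""
    hi = total if hi is None else hi
    start = lo + ((hi - lo) - length) // 2 + int(
        rng.integers(-center_jitter, center_jitter + 1))
    return int(np.clip(start, lo, hi - length))


def generate_patient(spec: PhantomSpec, grade: int,
                     rng: np.random.Generator,
                     patient_id: str = "phantom-000") -> VolumeStack:
    """Generate one graded phantom stack.

    The gland run sits near the middle of the stack (jitter +/- 2 slices)
    and the lesion run near the middle of the gland (jitter +/- 1), the
    typical situation for an index lesion; the inference loop's median-slice
    start is therefore usually, but not always, inside or adjacent to the
    lesion run.
    """
    if grade not in range(1, 6):
        raise ValueError(f"grade must be an integer in 1..5, got {grade!r}")

    n = int(rng.integers(spec.slices_per_patient[0],
                         spec.slices_per_patient[1] + 1))
    gland = int(rng.integers(spec.gland_slices[0], spec.gland_slices[1] + 1))
    lesion = int(rng.integers(spec.lesion_slices[0],
                              min(gland, spec.lesion_slices[1]) + 1))
    g0 = _place_run(n, gland, center_jitter=2, rng=rng)
    l0 = _place_run(n, lesion, center_jitter=1, rng=rng,
                    lo=g0, hi=g0 + gland)

    size = spec.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = size / 2.0
    gland_r = 0.22 * size
    lesion_r = 0.08 * size
    # Index-lesion position: stereotyped posterior-lateral site with small
    # per-patient anatomic jitter.  The jitter is kept small (+/- 2% of the
    # field of view) so that signal_separation, not lesion position, is the
    # factor controlling how distinguishable the grades are.
    ly = cy + (0.05 + rng.uniform(-0.02, 0.02)) * size
    lx = cx + (-0.04 + rng.uniform(-0.02, 0.02)) * size
    gland_mask = (yy - cy) ** 2 + (xx - cx) ** 2 < gland_r ** 2
    lesion_mask = (yy - ly) ** 2 + (xx - lx) ** 2 < lesion_r ** 2

    minor = None
    if spec.second_lesion_prob > 0 and rng.random() < spec.second_lesion_prob:
        # small second lesion at a different grade, on a disjoint slice run
        minor_grade = int(rng.choice([g for g in range(1, 6) if g != grade]))
        minor_len = max(2, lesion // 2)
        if l0 - g0 >= minor_len:                    # below the index lesion
            m0 = g0
        else:                                       # above it
            m0 = min(g0 + gland, l0 + lesion + minor_len) - minor_len
        my = cy - rng.uniform(0.05, 0.1) * size
        mx = cx + rng.uniform(-0.05, 0.05) * size
        mmask = (yy - my) ** 2 + (xx - mx) ** 2 < (0.6 * lesion_r) ** 2
        minor = (minor_grade, m0, m0 + minor_len, mmask)

    slices = np.empty((n, size, size), dtype=np.float32)
    flags = np.zeros(n, dtype=bool)
    masks: dict[int, np.ndarray] = {}
    for i in range(n):
        zfrac = i / max(n - 1, 1)
        img = (0.15 + 0.10 * zfrac
               + 0.02 * rng.standard_normal((size, size)))
        if g0 <= i < g0 + gland:
            img[gland_mask] += 0.25
            if l0 <= i < l0 + lesion:
                flags[i] = True
                _paint_lesion(img, lesion_mask, grade,
                              spec.signal_separation, xx, yy)
                masks[i] = lesion_mask.copy()
            if minor is not None and minor[1] <= i < minor[2]:
                flags[i] = True
                _paint_lesion(img, minor[3], minor[0],
                              spec.signal_separation, xx, yy)
                masks[i] = masks.get(i, np.zeros_like(gland_mask)) | minor[3]
        img += spec.noise_sd * rng.standard_normal((size, size))
        slices[i] = img
    gg_nb = _sample_nb_grade(grade, spec.nb_kernel, rng)
    return VolumeStack(patient_id=patient_id, slices=slices,
                       tumor_flags=flags, gg_rp=grade, gg_nb=gg_nb,
                       lesion_masks=masks)


def assign_split(index: int) -> str:
    """Deterministic 70/10/20 split by patient index (index mod 10)."""
    r = index % 10
    if r < 7:
        return "train"
    if r == 7:
        return "val"
    return "test"


def draw_grades(grade_probs, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. grade labels (1..5) from the class prior."""
    return rng.choice(np.arange(1, 6), size=n,
                      p=np.asarray(grade_probs, dtype=np.float64))


def generate_cohort(spec: PhantomSpec):
    """Generate ``spec.n_patients`` phantoms plus a manifest table.

    Grade labels are drawn i.i.d. from ``spec.grade_probs``.  Returns
    ``(stacks, manifest)`` where the manifest has one row per patient with
    columns patient_id, path (filled by :func:`write_fixture`), gg_rp,
    gg_nb, split and tumor_flags (a compact 0/1 string).
    """
    rng = np.random.default_rng(spec.seed)
    grades = draw_grades(spec.grade_probs, spec.n_patients, rng)
    stacks, rows = [], []
    for i, g in enumerate(grades):
        pid = f"phantom-{i:04d}"
        stack = generate_patient(spec, int(g), rng, patient_id=pid)
        stacks.append(stack)
        rows.append({
            "patient_id": pid,
            "path": "",
            "gg_rp": int(stack.gg_rp),
            "gg_nb": int(stack.gg_nb),
            "split": assign_split(i),
            "tumor_flags": "".join("1" if f else "0"
                                   for f in stack.tumor_flags),
        })
    manifest = pd.DataFrame(rows)
    return stacks, manifest


def write_fixture(stacks: list[VolumeStack], manifest: pd.DataFrame,
                  directory, fmt: str = "npz") -> Path:
    """Serialize a cohort; returns the manifest CSV path.

    ``npz`` keeps slices, flags and lesion masks; ``nifti`` writes
    ``.nii.gz`` volumes (flags and labels live in the manifest).
    """
    from . import io as ggio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("npz", "nifti"):
        raise ValueError(f"unknown fixture format {fmt!r}")
    manifest = manifest.copy()
    for i, stack in enumerate(stacks):
        if fmt == "npz":
            path = directory / f"{stack.patient_id}.npz"
            ggio.write_npz(stack, path)
        else:
            path = directory / f"{stack.patient_id}.nii.gz"
            ggio.write_nifti(stack, path)
        manifest.loc[manifest["patient_id"] == stack.patient_id,
                     "path"] = path.name
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_fixture(manifest_path) -> tuple[list[VolumeStack], pd.DataFrame]:
    """Load a cohort written by :func:`write_fixture` (lossless round trip
    for intensities, tumor flags and grade labels)."""
    from . import io as ggio

    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, dtype={"tumor_flags": str})
    stacks = []
    for _, row in manifest.iterrows():
        stack = ggio.read_volume(manifest_path.parent / row["path"])
        stack.patient_id = row["patient_id"]
        stack.gg_rp = int(row["gg_rp"])
        stack.gg_nb = int(row["gg_nb"])
        flags = np.array([c == "1" for c in row["tumor_flags"]])
        if len(flags) != stack.n_slices:
            raise ValueError(
                f"{row['patient_id']}: {len(flags)} flags for "
                f"{stack.n_slices} slices")
        stack.tumor_flags = flags
        stacks.append(stack)
    return stacks, manifest
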