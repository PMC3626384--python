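"""Synthetic ventilation-MRI phantoms with ground truth.

Emulates the coronal multi-slice acquisition the pipeline targets: 256x256
in-plane, 8-14 slices, 1.8 mm pixels / 13 mm slices, background noise drawn
from the adjusted Rayleigh model, two elliptical lungs containing four
concentric intensity classes (negligible / low / intermediate / high
ventilation), optional zero-signal defect pockets, and a bright trachea
tube with bronchial stubs spanning the middle slices.

Ground truth accompanies every phantom: the ventilated-lung mask (low,
intermediate and high classes, minus defects), the airway mask, and the
per-pixel class label map.  Everything is reproducible from the seed.

The phantom emulates intensity structure and background statistics only —
no coil-sensitivity shading, partial-volume edges, gas-flow physics or
anatomically realistic airway trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .airway_removal import SeedSpec
from .image_io import ImageStack, MaskStack
from .noise_subtraction import sample_adjusted_rayleigh

__all__ = ["PhantomSpec", "Phantom", "generate", "end_to_end_fixture", "PRESETS"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity classes, defects and noise of a phantom."""

    n_slices: int = 10
    n_rows: int = 256
    n_cols: int = 256
    # two lungs as ellipses: (center_row, center_col, row_semi_axis, col_semi_axis)
    lung_centers: tuple[tuple[int, int], tuple[int, int]] = ((135, 82), (135, 174))
    lung_axes: tuple[int, int] = (62, 34)
    # trachea tube: rows, centre column, half-width, slice range [lo, hi)
    trachea_rows: tuple[int, int] = (28, 105)
    trachea_col: int = 128
    trachea_half_width: int = 5
    trachea_slices: tuple[int, int] | None = None  # default: middle 4 slices
    bronchi_rows: tuple[int, int] = (97, 104)
    bronchi_reach: int = 10  # horizontal stub length from the tube wall
    # intensity model
    class_levels: tuple[float, float, float, float] = (0.0, 60.0, 120.0, 200.0)
    class_fractions: tuple[float, float, float, float] = (0.1, 0.3, 0.3, 0.3)
    signal_jitter: float = 5.0
    noise_sigma: float = 10.0
    noise_alpha: float = 1.0
    noise_delta: float = 0.0
    blur_sigma: float = 0.0
    # zero-signal ventilation defects
    n_defects: int = 0
    defect_radius: tuple[int, int] = (4, 7)
    seed: int = 42

    def __post_init__(self) -> None:
        lv = self.class_levels
        if not (lv[0] < lv[1] < lv[2] < lv[3]):
            raise ValueError("class_levels must be strictly increasing")
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        for cr, cc in self.lung_centers:
            if (
                cr - self.lung_axes[0] < 0
                or cr + self.lung_axes[0] >= self.n_rows
                or cc - self.lung_axes[1] < 0
                or cc + self.lung_axes[1] >= self.n_cols
            ):
                raise ValueError("lung ellipse exceeds image bounds")
        # the trachea tube must stay clear of both lungs by >= 2 px
        tube_lo = self.trachea_col - self.trachea_half_width
        tube_hi = self.trachea_col + self.trachea_half_width
        for cr, cc in self.lung_centers:
            edge_lo, edge_hi = cc - self.lung_axes[1], cc + self.lung_axes[1]
            if edge_hi >= tube_lo - 2 and edge_lo <= tube_hi + 2:
                raise ValueError("trachea tube not separated from the lungs by >= 2 px")

    @property
    def middle_slices(self) -> tuple[int, int]:
        if self.trachea_slices is not None:
            return self.trachea_slices
        mid = self.n_slices // 2
        return (max(mid - 2, 0), min(mid + 2, self.n_slices))


@dataclass(frozen=True)
class Phantom:
    """A generated phantom bundle."""

    image: ImageStack
    truth: MaskStack          # ventilated airspaces (low/int/high minus defects)
    truth_airway: MaskStack   # trachea tube + bronchial stubs
    truth_labels: np.ndarray  # 0 background, 1..4 lung classes, 5 airway
    spec: PhantomSpec

    def seed_specs(self, margin: int = 22) -> list[SeedSpec]:
        """Airway seed/bounding-box sidecar: seed at the tube centre of each
        trachea-bearing slice, box enclosing tube and stubs with a margin."""
        s = self.spec
        lo, hi = s.middle_slices
        r0, r1 = s.trachea_rows
        seed_row = (r0 + r1) // 2
        c_lo = s.trachea_col - s.trachea_half_width - s.bronchi_reach - margin // 4
        c_hi = s.trachea_col + s.trachea_half_width + s.bronchi_reach + margin // 4
        bbox = (
            max(r0 - 6, 0),
            max(c_lo, 0),
            min(s.bronchi_rows[1] + 6, s.n_rows - 1),
            min(c_hi, s.n_cols - 1),
        )
        return [
            SeedSpec(slice_index=i, seed=(seed_row, s.trachea_col), bbox=bbox)
            for i in range(lo, hi)
        ]


def _lung_geometry(spec: PhantomSpec, slice_index: int) -> list[tuple[int, int, float, float]]:
    """Per-slice ellipse parameters; lungs taper toward the first/last slice."""
    depth = np.sin(np.pi * (slice_index + 0.5) / spec.n_slices)
    scale = 0.55 + 0.45 * depth
    a_r = spec.lung_axes[0] * scale
    a_c = spec.lung_axes[1] * scale
    return [(cr, cc, a_r, a_c) for cr, cc in spec.lung_centers]


def generate(spec: PhantomSpec) -> Phantom:
    """Generate a phantom; bit-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    shape = (spec.n_slices, spec.n_rows, spec.n_cols)
    rr, cc = np.meshgrid(np.arange(spec.n_rows), np.arange(spec.n_cols), indexing="ij")

    labels = np.zeros(shape, dtype=np.int16)
    img = np.zeros(shape, dtype=float)

    # radial class boundaries from the area fractions: innermost = high
    f_neg, f_low, f_int, f_high = spec.class_fractions
    rho_high = np.sqrt(f_high)
    rho_int = np.sqrt(f_high + f_int)
    rho_low = np.sqrt(f_high + f_int + f_low)

    lo, hi = spec.middle_slices
    tr0, tr1 = spec.trachea_rows
    br0, br1 = spec.bronchi_rows
    t_lo = spec.trachea_col - spec.trachea_half_width
    t_hi = spec.trachea_col + spec.trachea_half_width

    defect_centers: list[tuple[int, int, int, int]] = []  # (slice, row, col, radius)
    if spec.n_defects:
        # deterministic placement well inside the high/intermediate core of a
        # lung; distinct defect pockets never overlap (rejection sampling)
        for k in range(spec.n_defects):
            for _attempt in range(100):
                s_idx = int(rng.integers(lo, hi))
                lung = spec.lung_centers[int(rng.integers(0, 2))]
                ang = rng.uniform(0, 2 * np.pi)
                rad = int(rng.integers(spec.defect_radius[0], spec.defect_radius[1] + 1))
                rho = rng.uniform(0.1, 0.45)
                _, _, a_r, a_c = _lung_geometry(spec, s_idx)[0]
                drow = int(round(lung[0] + rho * a_r * np.sin(ang)))
                dcol = int(round(lung[1] + rho * a_c * np.cos(ang)))
                clear = all(
                    s != s_idx or (drow - r) ** 2 + (dcol - c) ** 2 > (rad + pr + 1) ** 2
                    for s, r, c, pr in defect_centers
                )
                if clear:
                    defect_centers.append((s_idx, drow, dcol, rad))
                    break
            else:
                raise ValueError("could not place non-overlapping defects")

    for i in range(spec.n_slices):
        # background everywhere, then paint lungs and airway over it
        img[i] = sample_adjusted_rayleigh(
            spec.n_rows * spec.n_cols,
            spec.noise_sigma,
            spec.noise_alpha,
            spec.noise_delta,
            rng,
        ).reshape(spec.n_rows, spec.n_cols)

        for cr, ccen, a_r, a_c in _lung_geometry(spec, i):
            rho = np.sqrt(((rr - cr) / a_r) ** 2 + ((cc - ccen) / a_c) ** 2)
            inside = rho <= 1.0
            cls = np.zeros_like(labels[i])
            cls[inside & (rho <= rho_high)] = 4
            cls[inside & (rho > rho_high) & (rho <= rho_int)] = 3
            cls[inside & (rho > rho_int) & (rho <= rho_low)] = 2
            cls[inside & (rho > rho_low)] = 1
            sel = cls > 0
            labels[i][sel] = cls[sel]
            levels = np.asarray((np.nan,) + spec.class_levels)  # index by class code
            signal = levels[cls[sel]] + rng.normal(0.0, spec.signal_jitter, size=int(sel.sum()))
            img[i][sel] = np.clip(signal, 0.0, None)

        if lo <= i < hi:
            tube = (
                (rr >= tr0) & (rr <= tr1) & (cc >= t_lo) & (cc <= t_hi)
            )
            stubs = (
                (rr >= br0)
                & (rr <= br1)
                & (
                    ((cc >= t_lo - spec.bronchi_reach) & (cc < t_lo))
                    | ((cc > t_hi) & (cc <= t_hi + spec.bronchi_reach))
                )
            )
            airway = tube | stubs
            labels[i][airway] = 5
            img[i][airway] = np.clip(
                spec.class_levels[3]
                + rng.normal(0.0, spec.signal_jitter, size=int(airway.sum())),
                0.0,
                None,
            )

    for s_idx, drow, dcol, rad in defect_centers:
        disk = (rr - drow) ** 2 + (cc - dcol) ** 2 <= rad**2
        labels[s_idx][disk] = 0
        img[s_idx][disk] = sample_adjusted_rayleigh(
            int(disk.sum()), spec.noise_sigma, spec.noise_alpha, spec.noise_delta, rng
        )

    if spec.blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        for i in range(spec.n_slices):
            img[i] = gaussian_filter(img[i], spec.blur_sigma)
        img = np.clip(img, 0.0, None)

    image = ImageStack(slices=img)
    truth = MaskStack.like(image, ((labels >= 2) & (labels <= 4)).astype(np.uint8))
    truth_airway = MaskStack.like(image, (labels == 5).astype(np.uint8))
    return Phantom(
        image=image, truth=truth, truth_airway=truth_airway, truth_labels=labels, spec=spec
    )


PRESETS: dict[str, PhantomSpec] = {
    # the negligible class sits just above the noise floor, as in real
    # ventilation images; SNR decreases easy -> realistic -> hard
    "easy": PhantomSpec(
        class_levels=(45.0, 90.0, 150.0, 210.0),
        signal_jitter=2.0,
        noise_sigma=5.0,
        n_defects=0,
    ),
    "realistic": PhantomSpec(
        class_levels=(45.0, 90.0, 150.0, 210.0),
        signal_jitter=5.0,
        noise_sigma=10.0,
        n_defects=3,
    ),
    "hard": PhantomSpec(
        class_levels=(30.0, 60.0, 110.0, 180.0),
        signal_jitter=10.0,
        noise_sigma=20.0,
        n_defects=5,
    ),
}


def end_to_end_fixture(level: str = "realistic", seed: int | None = None) -> tuple[Phantom, list[SeedSpec]]:
    """A preset phantom plus its airway seed sidecar."""
    if level not in PRESETS:
        raise ValueError(f"unknown preset {level!r}; choose from {sorted(PRESETS)}")
    spec = PRESETS[level]
    if seed is not None:
        spec = replace(spec, seed=seed)
    ph = generate(spec)
    return ph, ph.seed_specs()
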