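"""Synthetic glabella surfaces, profiles and landmark populations.

Everything downstream of the scanner can be exercised offline with these
generators, which plant known ground truth (extremum positions, mean shapes,
effect sizes) so recovery can be verified.

A glabella-like surface is modeled as a smooth axial dome carrying four
Gaussian lobe crests (L4..L1, anterior to posterior) separated by three
Gaussian transglabellar furrow grooves (TF3..TF1), with white Gaussian noise
at the instrument accuracy (1.5 um). Sharp versus rounded lobes and furrows
are governed by the Gaussian widths; setting a furrow depth to zero
reproduces the effaced ("obliterated furrow") preservation state. The study
generator emits three labeled populations of axial profiles with sizes
19 / 18 / 16 and population-specific furrow-depth and sharpness regimes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .landmarking import LandmarkConfiguration, N_LANDMARKS
from .profile_tools import Profile
from .surface_io import DEM

#: instrument accuracy, mm
INSTRUMENT_NOISE_SD = 0.0015
WINDOW_MM = 5.0
LINES = 1500

STUDY_POPULATIONS = ("China", "Siberia", "USA")
STUDY_SIZES = (19, 18, 16)


@dataclass
class GlabellaParams:
    """Parameters of one synthetic glabella surface.

    Lengths in mm. ``lobe_width_sigma`` controls the rounded (wide) versus
    sharp (narrow) typology; ``furrow_depths`` of 0 efface a furrow. Lobe
    bumps are kept wider than half their spacing (defaults: sigma = 0.6 x
    length/4) so that adjacent lobes merge into a smooth crest unless a
    furrow groove separates them — effacing a furrow genuinely removes the
    corresponding extrema, as in the fossils, rather than leaving a residual
    dip between free-standing bumps.
    """

    length: float = 3.0
    lobe_amplitudes: tuple[float, ...] = (0.06, 0.08, 0.09, 0.11)  # L4..L1
    furrow_depths: tuple[float, ...] = (0.03, 0.035, 0.04)         # TF3..TF1
    lobe_width_sigma: float = 0.45
    furrow_width_sigma: float = 0.19
    dome_height: float = 0.35
    dome_width_factor: float = 0.75  # dome half-width = factor * length
    noise_sd: float = INSTRUMENT_NOISE_SD
    seed: int = 0
    n_grid: int = LINES
    window: float = WINDOW_MM

    def __post_init__(self):
        if len(self.lobe_amplitudes) != 4 or len(self.furrow_depths) != 3:
            raise ValueError("need 4 lobe amplitudes and 3 furrow depths")
        if any(a < 0 for a in self.lobe_amplitudes) or any(d < 0 for d in self.furrow_depths):
            raise ValueError("amplitudes and depths must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.length <= self.window:
            raise ValueError("glabella length must be positive and fit the scan window")

    @property
    def lobe_centers(self) -> np.ndarray:
        """Axial positions of the 4 lobe crests, centered in the window."""
        start = 0.5 * (self.window - self.length)
        return start + (np.arange(4) + 0.5) / 4.0 * self.length

    @property
    def furrow_centers(self) -> np.ndarray:
        """Axial positions of the 3 furrows (between consecutive lobes)."""
        start = 0.5 * (self.window - self.length)
        return start + np.arange(1, 4) / 4.0 * self.length


def axial_elevation(params: GlabellaParams, s: np.ndarray) -> np.ndarray:
    """Noise-free elevation along the axial midline at positions ``s`` (mm).

    The dome is a flat-topped super-Gaussian: essentially level across the
    lobe region (so lobes and furrows own the interior extrema) and falling
    off steeply just beyond L4 and L1, like the glabella dropping to the
    preglabellar field and occipital ring.
    """
    mid = 0.5 * params.window
    u = (s - mid) / (params.dome_width_factor * params.length)
    z = params.dome_height * np.exp(-0.5 * u ** 6)
    for c, a in zip(params.lobe_centers, params.lobe_amplitudes):
        z = z + a * np.exp(-0.5 * ((s - c) / params.lobe_width_sigma) ** 2)
    for c, d in zip(params.furrow_centers, params.furrow_depths):
        z = z - d * np.exp(-0.5 * ((s - c) / params.furrow_width_sigma) ** 2)
    return z


def true_landmarks(params: GlabellaParams, n_fine: int = 20001) -> np.ndarray:
    """Planted 7-landmark ground truth: (7, 2) array of (s, z) along the axis.

    Extrema of the noise-free axial function, found on a fine grid: the 4
    lobe maxima and the minimum between each consecutive pair. Effaced
    furrows (depth 0 with overlapping lobes) may merge extrema; the returned
    array then contains the surviving extrema only (fewer than 7 rows).
    """
    lo = params.lobe_centers[0] - 3 * params.lobe_width_sigma
    hi = params.lobe_centers[-1] + 3 * params.lobe_width_sigma
    s = np.linspace(max(lo, 0), min(hi, params.window), n_fine)
    z = axial_elevation(params, s)
    interior = np.arange(1, len(s) - 1)
    is_max = (z[interior] > z[interior - 1]) & (z[interior] > z[interior + 1])
    maxima = interior[is_max]
    if len(maxima) == 0:
        return np.empty((0, 2))
    # rank by height and keep at most 4, in axial order
    maxima = maxima[np.argsort(z[maxima])[::-1][:4]]
    maxima = np.sort(maxima)
    rows = [(s[maxima[0]], z[maxima[0]])]
    for a, b in zip(maxima[:-1], maxima[1:]):
        seg = slice(a + 1, b)
        m = a + 1 + int(np.argmin(z[seg]))
        if z[m] < z[a] and z[m] < z[b]:
            rows.append((s[m], z[m]))
        rows.append((s[b], z[b]))
    return np.array(rows)


def simulate_glabella_dem(params: GlabellaParams) -> tuple[DEM, np.ndarray]:
    """Synthetic scan of a glabella: DEM plus planted landmark ground truth.

    The surface is the axial elevation profile modulated across the axis by a
    Gaussian envelope (the glabella stands proud of a flat field), sampled on
    an ``n_grid`` x ``n_grid`` grid over the scan window, plus white noise.
    The axial line runs along y at x = window/2. Ground truth is the (m, 2)
    table of true extremum positions from :func:`true_landmarks`.
    """
    # warn when a groove would cut below the base plane (furrow swallows lobe)
    base = axial_elevation(
        GlabellaParams(**{**params.__dict__, "furrow_depths": (0.0, 0.0, 0.0),
                          "noise_sd": 0.0}),
        params.furrow_centers)
    if np.any(np.asarray(params.furrow_depths) > base):
        warnings.warn("a furrow is deeper than the adjacent lobes' envelope")
    n = params.n_grid
    cell = params.window / n
    centers = (np.arange(n) + 0.5) * cell
    z_axial = axial_elevation(params, centers)          # along y
    cross = np.exp(-0.5 * ((centers - 0.5 * params.window) / (0.35 * params.window)) ** 2)
    surface = np.outer(z_axial, cross)                  # rows = y, cols = x
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        surface = surface + rng.normal(0.0, params.noise_sd, size=surface.shape)
    dem = DEM(surface, origin_x=0.0, origin_y=0.0, cell_size=cell)
    return dem, true_landmarks(params)


@dataclass
class PopulationSpec:
    """A landmark population: mean shape + tangent-space dispersion."""

    mean_shape: np.ndarray            # (7, 2)
    dispersion: float | np.ndarray = 0.01  # isotropic SD or (14, 14) covariance
    n: int = 10
    label: str = ""
    seed: int = 0

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.mean_shape.shape != (N_LANDMARKS, 2):
            raise ValueError(f"mean_shape must be ({N_LANDMARKS}, 2)")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not np.isscalar(self.dispersion):
            cov = np.asarray(self.dispersion, dtype=float)
            if cov.shape != (2 * N_LANDMARKS, 2 * N_LANDMARKS):
                raise ValueError("covariance must be (14, 14)")
            evals = np.linalg.eigvalsh(0.5 * (cov + cov.T))
            if evals.min() < -1e-10 * max(evals.max(), 1.0):
                raise ValueError("dispersion covariance must be positive semidefinite")


def simulate_population(spec: PopulationSpec) -> list[LandmarkConfiguration]:
    """Draw configurations around a mean shape, then hide the alignment.

    Shape noise is Gaussian around the mean (isotropic SD per coordinate or a
    full 14 x 14 covariance); each specimen then receives a random rotation,
    translation and scale so the Procrustes fit has real work to do. With
    dispersion 0 all specimens share the mean's shape exactly.
    """
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n):
        if np.isscalar(spec.dispersion):
            noise = rng.normal(0.0, float(spec.dispersion), size=(N_LANDMARKS, 2))
        else:
            cov = np.asarray(spec.dispersion, dtype=float)
            noise = rng.multivariate_normal(np.zeros(2 * N_LANDMARKS),
                                            0.5 * (cov + cov.T)).reshape(N_LANDMARKS, 2)
        shape = spec.mean_shape + noise
        theta = rng.uniform(-np.pi, np.pi)
        R = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
        scale = rng.uniform(0.5, 2.0)
        shift = rng.uniform(-10.0, 10.0, size=2)
        out.append(LandmarkConfiguration(scale * (shape @ R) + shift,
                                         specimen_id=f"{spec.label or 'sim'}_{i:03d}",
                                         population=spec.label))
    return out


# ------------------------------------------------------------- study bundle

@dataclass
class StudyBundle:
    """Three labeled populations of axial profiles with planted ground truth."""

    profiles: list[Profile]
    labels: list[str]
    params: list[GlabellaParams]
    ground_truth: list[np.ndarray]  # per specimen, (m, 2) true extrema

    def by_population(self, label: str) -> list[Profile]:
        return [p for p, l in zip(self.profiles, self.labels) if l == label]

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = []
        rows = []
        for p, l in zip(self.profiles, self.labels):
            f = out_dir / f"{p.specimen_id}.csv"
            with open(f, "w") as fh:
                p.to_csv(fh)
            written.append(f)
            rows.append(f"{p.specimen_id},{l}")
        lab = out_dir / "labels.csv"
        lab.write_text("specimen,population\n" + "\n".join(rows) + "\n")
        written.append(lab)
        return written


def _study_params(pop: str, i: int, rng: np.random.Generator) -> GlabellaParams:
    """Per-specimen surface parameters under a population's regime.

    USA: deep furrows, wide (rounded) lobes; Siberia: shallow, sometimes
    effaced furrows, narrow (sharp) lobes, homogeneous relief; China: a
    mixture of both regimes with the widest relief spread.
    """
    length = float(rng.uniform(1.5, 5.0))
    u = length / 3.0   # depths, amplitudes and dome scale with glabellar size
    d = length / 4.0   # lobe spacing
    if pop == "USA":
        depth = rng.uniform(0.045, 0.07, 3)
        sigma, fsigma = 0.70 * d, 0.30 * d   # rounded lobes, rounded furrows
        relief = rng.normal(1.0, 0.10)
    elif pop == "Siberia":
        depth = rng.uniform(0.025, 0.04, 3)
        # occasionally efface TF2/TF3 entirely (the disputed character)
        if rng.uniform() < 0.25:
            depth[:2] = 0.0
        sigma, fsigma = 0.55 * d, 0.20 * d   # sharp lobes, sharp furrows
        relief = rng.normal(0.80, 0.04)      # narrow, low relief range
    else:  # China: mixed preservation, widest relief spread
        if rng.uniform() < 0.5:
            depth = rng.uniform(0.04, 0.07, 3)
            sigma, fsigma = 0.68 * d, 0.28 * d
        else:
            depth = rng.uniform(0.025, 0.04, 3)
            sigma, fsigma = 0.56 * d, 0.20 * d
        relief = rng.normal(1.25, 0.20)
    relief = float(np.clip(relief, 0.5, 2.0))
    amps = rng.uniform(0.06, 0.085, 4)
    return GlabellaParams(length=length,
                          lobe_amplitudes=tuple(amps * u * relief),
                          furrow_depths=tuple(depth * u * relief),
                          lobe_width_sigma=float(sigma),
                          furrow_width_sigma=float(fsigma),
                          dome_height=float(0.35 * u * relief),
                          noise_sd=INSTRUMENT_NOISE_SD,
                          seed=int(rng.integers(2 ** 31)))


def simulate_study(seed: int = 0, n_samples: int = LINES,
                   sizes: tuple[int, int, int] = STUDY_SIZES) -> StudyBundle:
    """Generate the full three-population axial-profile study bundle.

    Populations and sizes follow the scanned samples: China n=19, Siberia
    n=18, USA n=16. Each specimen gets an axial elevation profile across the
    scan window with instrument noise, plus its planted landmark positions.
    """
    rng = np.random.default_rng(seed)
    profiles, labels, plist, truth = [], [], [], []
    for pop, n_pop in zip(STUDY_POPULATIONS, sizes):
        for i in range(n_pop):
            params = _study_params(pop, i, rng)
            s = np.linspace(0.0, params.window, n_samples)
            z = axial_elevation(params, s)
            z = z + np.random.default_rng(params.seed).normal(0, params.noise_sd, n_samples)
            profiles.append(Profile(s=s, z=z, specimen_id=f"{pop}_{i:03d}",
                                    orientation="sagittal"))
            labels.append(pop)
            plist.append(params)
            truth.append(true_landmarks(params))
    return StudyBundle(profiles=profiles, labels=labels, params=plist,
                       ground_truth=truth)
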