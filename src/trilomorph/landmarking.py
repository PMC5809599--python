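"""Profile landmarking: lobe/furrow detection, sharpness scoring, TPS I/O.

Seven landmarks describe a glabellar elevation profile, ordered anterior to
posterior: the four lobe crests L4, L3, L2, L1 (local elevation maxima) and
the three transglabellar furrows TF3, TF2, TF1 (local minima between
consecutive lobes), i.e. index 1..7 = L4, TF3, L3, TF2, L2, TF1, L1.

Detection is automatic and reproducible — prominence-ranked extrema with an
alternation guarantee — but manually digitized landmarks supplied as TPS files
take precedence over the automatic rule wherever both exist.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import IO, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import (BoundsError, CardinalityError, FormatError,
                     InsufficientReliefError)
from .profile_tools import Profile

N_LANDMARKS = 7
LANDMARK_NAMES = ("L4", "TF3", "L3", "TF2", "L2", "TF1", "L1")
#: lobe landmarks are maxima, furrow landmarks minima
LANDMARK_ROLES = ("lobe", "furrow", "lobe", "furrow", "lobe", "furrow", "lobe")

#: default minimum prominence = 2x the instrument accuracy (1.5 um), in mm,
#: so measurement noise cannot create a furrow
DEFAULT_MIN_PROMINENCE = 0.003
#: default smoothing window as a fraction of the sample count
DEFAULT_SMOOTH_FRACTION = 0.02


@dataclass
class LandmarkConfiguration:
    """7 ordered 2-D landmarks for one specimen.

    ``coords`` is (7, 2): column 0 = u (distance along profile, mm), column 1
    = v (elevation, mm) when digitized from a profile; after arbitrary
    similarity transforms (e.g. simulated specimens) the axes lose that
    meaning and u need not be monotone — use :meth:`is_profile_ordered`.
    """

    coords: np.ndarray
    specimen_id: str = ""
    population: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_LANDMARKS, 2):
            raise ValueError(f"coords must be ({N_LANDMARKS}, 2)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def is_profile_ordered(self) -> bool:
        """True when u is strictly increasing (anterior -> posterior)."""
        return bool(np.all(np.diff(self.coords[:, 0]) > 0))


@dataclass
class SharpnessReport:
    """Curvature-based lobe/furrow typology for one landmarked profile.

    ``curvature`` holds the signed second derivative of a local quadratic fit
    at each landmark (1/mm; negative at lobe crests, positive in furrows);
    ``classes`` labels each as "sharp" or "rounded" relative to ``threshold``.
    """

    curvature: np.ndarray          # (7,)
    classes: tuple[str, ...]       # (7,) "sharp" | "rounded"
    threshold: float
    names: tuple[str, ...] = LANDMARK_NAMES
    roles: tuple[str, ...] = LANDMARK_ROLES


def _moving_average(z: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return z.copy()
    pad = window // 2
    zp = np.pad(z, pad, mode="edge")
    sm = np.convolve(zp, np.ones(window) / window, mode="same")[pad:pad + len(z)]
    return sm


def detect_landmarks(p: Profile, smoothing_window: int | None = None,
                     min_prominence: float = DEFAULT_MIN_PROMINENCE) -> LandmarkConfiguration:
    """Automatic placement of the 7 lobe/furrow landmarks on a profile.

    The profile is smoothed with a centered moving average (default window =
    2 % of the sample count), the 4 most prominent local maxima become the
    lobes, and the deepest point between consecutive lobes becomes a furrow —
    provided it lies at least ``min_prominence`` below both flanking crests.
    Anything less is treated as an effaced (obliterated) furrow and raises
    :class:`InsufficientReliefError` reporting what was found.
    """
    if len(p) < N_LANDMARKS:
        raise ValueError(f"profile needs at least {N_LANDMARKS} samples")
    if smoothing_window is None:
        smoothing_window = max(1, int(round(DEFAULT_SMOOTH_FRACTION * len(p))))
    zs = _moving_average(p.z, smoothing_window)
    peaks, props = find_peaks(zs, prominence=min_prominence)
    if len(peaks) < 4:
        raise InsufficientReliefError(
            f"only {len(peaks)} lobe maxima resolved (need 4); "
            "relief insufficient or furrows obliterated",
            n_maxima=len(peaks), n_minima=0)
    top4 = peaks[np.sort(np.argsort(props["prominences"])[-4:])]
    top4 = np.sort(top4)
    minima = []
    for a, b in zip(top4[:-1], top4[1:]):
        seg = zs[a + 1:b]
        if len(seg) == 0:
            continue
        m = a + 1 + int(np.argmin(seg))
        depth = min(zs[a], zs[b]) - zs[m]
        if depth >= min_prominence:
            minima.append(m)
    if len(minima) < 3:
        raise InsufficientReliefError(
            f"only {len(minima)} furrow minima of sufficient depth between the "
            "4 lobe maxima (need 3); furrow(s) effaced",
            n_maxima=4, n_minima=len(minima))
    idx = np.sort(np.concatenate([top4, minima]))
    coords = np.column_stack([p.s[idx], p.z[idx]])
    return LandmarkConfiguration(coords, specimen_id=p.specimen_id)


def sharpness_report(p: Profile, lm: LandmarkConfiguration,
                     half_window: float | None = None,
                     threshold: float | None = None) -> SharpnessReport:
    """Classify each landmark as sharp or rounded from local curvature.

    A quadratic is fit to the profile over ``u +- half_window`` (default 5 %
    of the profile length) around each landmark; the proxy is its second
    derivative. ``threshold`` defaults to the median |curvature| of the 7
    landmarks (data-adaptive); it is echoed in the report.
    """
    if half_window is None:
        half_window = 0.05 * p.length
    curv = np.empty(N_LANDMARKS)
    for i, (u, _) in enumerate(lm.coords):
        if u - half_window < p.s[0] - 1e-12 or u + half_window > p.s[-1] + 1e-12:
            raise BoundsError(
                f"window [{u - half_window:.4g}, {u + half_window:.4g}] around "
                f"landmark {LANDMARK_NAMES[i]} falls outside the profile")
        sel = (p.s >= u - half_window) & (p.s <= u + half_window)
        if sel.sum() < 3:
            raise BoundsError(f"fewer than 3 samples in the window at {LANDMARK_NAMES[i]}")
        a = np.polyfit(p.s[sel] - u, p.z[sel], 2)[0]
        curv[i] = 2.0 * a
    thr = float(np.median(np.abs(curv))) if threshold is None else float(threshold)
    classes = tuple("sharp" if abs(c) > thr else "rounded" for c in curv)
    return SharpnessReport(curvature=curv, classes=classes, threshold=thr)


# ---------------------------------------------------------------- TPS I/O

def read_tps(stream: IO[str] | str) -> list[LandmarkConfiguration]:
    """Read TPS landmark records (LM=7 each).

    ``ID=`` carries the specimen id; the convention ``ID=<specimen>__<population>``
    carries the population label. ``SCALE=`` (if present) multiplies the
    coordinates. v-coordinates are in math orientation (y up).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream]
    configs: list[LandmarkConfiguration] = []
    i, rec = 0, 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise FormatError(f"line {i + 1}: expected 'LM=' record header, got {line!r}")
        rec += 1
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError:
            raise FormatError(f"record {rec}: malformed LM= header {line!r}") from None
        if n_lm != N_LANDMARKS:
            raise CardinalityError(f"record {rec}: LM={n_lm}, expected {N_LANDMARKS}")
        i += 1
        coords = []
        while len(coords) < n_lm:
            if i >= len(lines) or "=" in lines[i]:
                raise FormatError(f"record {rec}: truncated after {len(coords)} "
                                  f"of {n_lm} coordinate lines")
            parts = lines[i].split()
            if len(parts) != 2:
                raise FormatError(f"record {rec}, line {i + 1}: expected 2 coordinates")
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise FormatError(f"record {rec}, line {i + 1}: non-numeric coordinate") from None
            i += 1
        spec_id, pop, scale = "", "", 1.0
        while i < len(lines) and "=" in lines[i] and not lines[i].strip().upper().startswith("LM="):
            key, _, val = lines[i].strip().partition("=")
            key = key.strip().upper()
            if key == "ID":
                spec_id = val.strip()
                if "__" in spec_id:
                    spec_id, pop = spec_id.rsplit("__", 1)
            elif key == "SCALE":
                try:
                    scale = float(val)
                except ValueError:
                    raise FormatError(f"record {rec}: non-numeric SCALE") from None
            i += 1
        arr = np.asarray(coords, dtype=float) * scale
        configs.append(LandmarkConfiguration(arr, specimen_id=spec_id, population=pop))
    if not configs:
        raise FormatError("no TPS records found")
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], stream: IO[str]) -> None:
    """Write TPS records; inverse of :func:`read_tps` (bit-identical round-trip)."""
    for c in configs:
        stream.write(f"LM={N_LANDMARKS}\n")
        for u, v in c.coords:
            stream.write(f"{float(u)!r} {float(v)!r}\n")
        ident = c.specimen_id + (f"__{c.population}" if c.population else "")
        stream.write(f"ID={ident}\n")


def configs_to_csv(configs: Sequence[LandmarkConfiguration], stream: IO[str]) -> None:
    """Flat CSV export: specimen,population,u1,v1,...,u7,v7."""
    cols = ",".join(f"u{i + 1},v{i + 1}" for i in range(N_LANDMARKS))
    stream.write(f"specimen,population,{cols}\n")
    for c in configs:
        flat = ",".join(repr(float(x)) for x in c.coords.ravel())
        stream.write(f"{c.specimen_id},{c.population},{flat}\n")
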