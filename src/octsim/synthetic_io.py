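"""Synthetic calibration/imaging experiments and delimited-text I/O.

Two experiment generators emulate the system's calibration measurements:

* a power-vs-angle sweep of a mirror around normal incidence (default
  -1°…1° in 5-arc-minute steps, six repeats, multiplicative power-meter
  noise), and
* through-focus B-scan series of a tilted mirror (11 stage positions) or a
  coverglass slab (7 positions) with additive spectral noise.

All randomness flows through one seeded generator per recipe, so identical
recipes produce byte-identical files.  Every series carries sidecar
ground-truth metadata (true tilt, thickness, per-A-scan fringe frequencies,
focus-coincidence stage position) sufficient to score any recovery without
re-reading the configuration.

Files are tab-separated UTF-8 text with a single header line naming the
columns and '#'-prefixed comment lines for metadata.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beam_optics import BeamParameters, WavenumberGrid
from .calibration import (DEFAULT_K0, DEFAULT_SURFACE_X3, PowerAngleDataset,
                          power_angle_model)
from .interferometry import (AScan, BScan, SystemGeometry, simulate_ascan,
                             stationary_depth)
from .sample_model import LayeredSample

__all__ = [
    "ExperimentRecipe",
    "FocusSeries",
    "default_wavenumber_grid",
    "default_focus_setup",
    "generate_power_angle",
    "generate_focus_series",
    "read_table",
    "write_table",
    "write_bscan",
    "read_bscan",
    "save_focus_series",
    "load_focus_series",
]


def default_wavenumber_grid() -> WavenumberGrid:
    """The swept-source sweep: 700 samples on [4.7835, 4.8973] μm⁻¹."""
    return WavenumberGrid(kmin=4.7835, kmax=4.8973, count=700)


@dataclass(frozen=True)
class ExperimentRecipe:
    """Conditions of a synthetic experiment.

    Power-angle defaults reproduce the goniometer sweep (25 angles from -1°
    to 1°, i.e. 5-arc-minute steps, measured 6 times); focus-series defaults
    reproduce the motorized-stage runs (11 positions for the mirror, 7 for
    the coverglass, ~2.75° tilt).  Noise: multiplicative Gaussian on power
    readings, additive Gaussian on spectra (relative to the series peak).
    """

    kind: str = "power_angle"
    seed: int = 0
    # power-vs-angle sweep
    angle_min_deg: float = -1.0
    angle_max_deg: float = 1.0
    n_angles: int = 25
    repeats: int = 6
    multiplicative_sd: float = 0.01
    # through-focus series
    n_stage_positions: int = 11
    stage_halfspan: float = 500.0
    n_ascans: int = 15
    lateral_step: float = 19.6
    additive_sd_rel: float = 0.005

    def __post_init__(self):
        if self.kind not in ("power_angle", "focus_series"):
            raise ValueError("kind must be power_angle or focus_series")
        if self.multiplicative_sd < 0 or self.additive_sd_rel < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.linspace(self.angle_min_deg, self.angle_max_deg,
                           self.n_angles)

    @property
    def stage_offsets(self) -> np.ndarray:
        return np.linspace(-self.stage_halfspan, self.stage_halfspan,
                           self.n_stage_positions)

    @property
    def lateral_positions(self) -> np.ndarray:
        x = np.arange(self.n_ascans, dtype=float) * self.lateral_step
        return x - x.mean()


def generate_power_angle(recipe: ExperimentRecipe, true_params,
                         k0: float = DEFAULT_K0,
                         surface_x3: float = DEFAULT_SURFACE_X3
                         ) -> PowerAngleDataset:
    """Synthesize a power-vs-angle dataset from the forward model.

    ``true_params`` is the generating pair (w0 [μm], θmax [deg]).  Each of
    the ``repeats`` sweeps receives independent multiplicative Gaussian
    noise; the returned dataset holds per-angle mean and standard
    deviation.  Zero noise reproduces the model evaluation exactly.
    """
    w0, theta_max = true_params
    angles = recipe.angles_deg
    model = power_angle_model(angles, w0, theta_max, k0=k0,
                              surface_x3=surface_x3)
    if recipe.multiplicative_sd == 0:
        return PowerAngleDataset(angles_deg=angles, power=model,
                                 std=np.zeros_like(model),
                                 repeats=recipe.repeats)
    rng = np.random.default_rng(recipe.seed)
    noise = rng.normal(1.0, recipe.multiplicative_sd,
                       size=(recipe.repeats, angles.size))
    reps = model[None, :] * noise
    return PowerAngleDataset(angles_deg=angles, power=reps.mean(axis=0),
                             std=reps.std(axis=0), repeats=recipe.repeats)


def default_focus_setup(tilt_deg: float = 2.75, theta0_center: float = 1300.0,
                        w0: float = 14.15, theta_max_deg: float = 1.5709,
                        r_detector: float = 500.0, r0: float = -1000.0,
                        search_halfspan: float = 600.0):
    """Beam/geometry/sample-center placement for a through-focus series.

    Places the sample-surface centre xΩ,3 at the model's focus-coincidence
    position — the surface depth maximizing the detected amplitude, found
    by a bounded search of the acceptance-filtered field magnitude at the
    central wavenumber (it lies within a Rayleigh-length scale of the
    nominal beam focus r0) — and chooses the reference-mirror coordinate so
    the fringe frequency at the centre is ``theta0_center``.  Returns
    ``(beam, geometry, x3_center)``.
    """
    from scipy.optimize import minimize_scalar

    from .scattering import AcceptanceSet, scattered_field_near

    beam = BeamParameters(w0=w0, r0=r0)
    kbar = default_wavenumber_grid().kbar
    xd = np.array([0.0, 0.0, r_detector])

    def neg_amplitude(x3):
        sample = LayeredSample.mirror(tilt_deg=tilt_deg, surface_x3=float(x3))
        B = AcceptanceSet(theta_max_deg, sample.normal, kbar)
        return -abs(scattered_field_near(sample, beam, kbar, xd, domain=B))

    res = minimize_scalar(neg_amplitude,
                          bounds=(r0 - search_halfspan, r0 + search_halfspan),
                          method="bounded", options={"xatol": 1.0})
    x3_center = float(res.x)
    t = np.deg2rad(tilt_deg)
    cos2t = np.cos(2.0 * t)
    x_ref = (theta0_center + (1.0 + cos2t) * x3_center
             + (1.0 - cos2t) * r0) / 2.0
    geometry = SystemGeometry(r_detector=r_detector, x_ref_mirror=float(x_ref),
                              theta_max_deg=theta_max_deg)
    return beam, geometry, x3_center


@dataclass
class FocusSeries:
    """A through-focus series of B-scans with sidecar ground truth."""

    bscans: list
    stage_offsets: np.ndarray
    metadata: dict


def _sample_at(kind: str, tilt_deg: float, x3: float, n1: float,
               thickness: float) -> LayeredSample:
    if kind == "mirror":
        return LayeredSample.mirror(tilt_deg=tilt_deg, surface_x3=x3)
    if kind == "coverglass":
        return LayeredSample.slab(n1=n1, thickness=thickness,
                                  tilt_deg=tilt_deg, surface_x3=x3)
    raise ValueError("sample kind must be mirror or coverglass")


def generate_focus_series(recipe: ExperimentRecipe, sample_kind: str,
                          beam: BeamParameters, geometry: SystemGeometry,
                          grid: WavenumberGrid, x3_center: float,
                          tilt_deg: float = 2.75, n1: float = 1.5088,
                          thickness: float = 150.0) -> FocusSeries:
    """Simulate a through-focus B-scan series with ground-truth sidecar.

    For every stage offset the sample surface is shifted along the depth
    axis; within a B-scan each A-scan is simulated in its own beam-centred
    frame, with the tilted surface's depth progressing as -tan(θΩ)·x1.
    Additive Gaussian noise (relative to the series' peak signal) is drawn
    from the recipe's seeded generator.
    """
    t = np.deg2rad(tilt_deg)
    cos2t = np.cos(2.0 * t)
    laterals = recipe.lateral_positions
    offsets = recipe.stage_offsets
    bscans = []
    truth_front, truth_back = [], []
    for off in offsets:
        ascans = []
        th_f_row, th_b_row = [], []
        for x1 in laterals:
            x3 = x3_center + off - np.tan(t) * x1
            sample = _sample_at(sample_kind, tilt_deg, x3, n1, thickness)
            ascans.append(simulate_ascan(sample, beam, geometry, grid,
                                         lateral_position=float(x1)))
            th0 = stationary_depth(x3, tilt_deg, beam.r0,
                                   geometry.x_ref_mirror)
            th_f_row.append(th0)
            if sample_kind == "coverglass":
                sin_t = np.sin(t) / n1
                cos_tt = np.sqrt(1.0 - sin_t**2)
                th_b_row.append(th0 + 2.0 * n1 * thickness * cos_tt)
        bscans.append(BScan(ascans=ascans))
        truth_front.append(th_f_row)
        truth_back.append(th_b_row)
    # additive detector noise, scaled to the strongest spectrum of the series
    peak = max(np.max(np.abs(a.values)) for b in bscans for a in b.ascans)
    if recipe.additive_sd_rel > 0:
        rng = np.random.default_rng(recipe.seed)
        for b in bscans:
            for a in b.ascans:
                a.values = a.values + rng.normal(
                    0.0, recipe.additive_sd_rel * peak, size=a.values.shape)
    # x3_center is placed at the model's confocal maximum (see
    # default_focus_setup), so the focus-coincidence stage is the one with
    # the smallest offset
    focus_idx = int(np.argmin(np.abs(offsets)))
    metadata = {
        "sample_kind": sample_kind,
        "tilt_deg": float(tilt_deg),
        "n1": float(n1) if sample_kind == "coverglass" else None,
        "thickness_um": float(thickness) if sample_kind == "coverglass" else None,
        "x3_center_um": float(x3_center),
        "stage_offsets_um": offsets.tolist(),
        "lateral_positions_um": laterals.tolist(),
        "focus_stage_index": focus_idx,
        "theta0_front_um": [list(map(float, r)) for r in truth_front],
        "theta0_back_um": ([list(map(float, r)) for r in truth_back]
                           if sample_kind == "coverglass" else None),
        "zero_delay_x3_um": float(geometry.x_ref_mirror),
        "seed": int(recipe.seed),
        "additive_sd": float(recipe.additive_sd_rel * peak),
    }
    return FocusSeries(bscans=bscans, stage_offsets=offsets,
                       metadata=metadata)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def write_table(path, frame: pd.DataFrame, metadata: dict | None = None):
    """Write a data frame as tab-separated text with '#' metadata lines."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_table(path, required_columns) -> pd.DataFrame:
    """Read a tab-separated table, validating the declared schema.

    Raises informative errors for empty files, missing columns and
    non-numeric cells (named by row and column).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    body = "\n".join(line for line in text.splitlines()
                     if line.strip() and not line.lstrip().startswith("#"))
    if not body:
        raise ValueError(f"empty input file: {path}")
    frame = pd.read_csv(io.StringIO(body), sep="\t",
                        float_precision="round_trip")
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    for col in required_columns:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column '{col}', row {bad[0]} of {path}")
        frame[col] = converted
    return frame


def write_bscan(path, bscan: BScan, metadata: dict | None = None):
    """Write a B-scan in long format (x1_um, k0_per_um, signal)."""
    rows = []
    for a in bscan.ascans:
        rows.append(pd.DataFrame({
            "x1_um": a.lateral_position,
            "k0_per_um": a.grid.k0,
            "signal": a.values,
        }))
    frame = pd.concat(rows, ignore_index=True)
    grid = bscan.ascans[0].grid
    meta = {"kmin": grid.kmin, "kmax": grid.kmax, "count": grid.count}
    meta.update(metadata or {})
    write_table(path, frame, metadata=meta)


def read_bscan(path) -> BScan:
    """Read a B-scan written by :func:`write_bscan`."""
    frame = read_table(path, ["x1_um", "k0_per_um", "signal"])
    ascans = []
    for x1, group in frame.groupby("x1_um", sort=True):
        k0 = group["k0_per_um"].to_numpy()
        grid = WavenumberGrid(kmin=float(k0.min()), kmax=float(k0.max()),
                              count=k0.size)
        ascans.append(AScan(grid=grid, values=group["signal"].to_numpy(),
                            lateral_position=float(x1)))
    return BScan(ascans=ascans)


def save_focus_series(directory, series: FocusSeries):
    """Write each B-scan as a TSV file plus a JSON ground-truth sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, b in enumerate(series.bscans):
        write_bscan(directory / f"bscan_{i:03d}.tsv", b,
                    metadata={"stage_offset_um": series.stage_offsets[i]})
    (directory / "ground_truth.json").write_text(
        json.dumps(series.metadata, indent=1), encoding="utf-8")


def load_focus_series(directory) -> FocusSeries:
    """Read a series written by :func:`save_focus_series`."""
    directory = Path(directory)
    meta = json.loads((directory / "ground_truth.json").read_text("utf-8"))
    files = sorted(directory.glob("bscan_*.tsv"))
    if not files:
        raise ValueError(f"no B-scan files in {directory}")
    bscans = [read_bscan(f) for f in files]
    return FocusSeries(bscans=bscans,
                       stage_offsets=np.asarray(meta["stage_offsets_um"]),
                       metadata=meta)
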