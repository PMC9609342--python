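"""Synthetic extraction-process Raman data generator.

Emulates a three-stage reflux extraction monitored by a dispersive Raman
probe: pure-component band profiles mixed linearly according to saturating
extraction kinetics, a smooth fluorescence-like baseline, replicate
acquisitions with i.i.d. noise, and a configurable number of planted gross
outliers.  Everything is reproducible from a single integer seed.

The default instrument axis runs 176-3500 cm^-1 at 2.83 cm^-1 resolution
(1175 channels); the default schedule yields 48 time points per batch
(18 + 15 + 15), i.e. 336 samples for 7 batches, with a ``drop_last`` flag
to trim to 335.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError, InvalidMeasurementError
from .spectra import ReferenceTable, SpectraMatrix

ATTRIBUTES = (
    "danshensu",
    "ferulic_acid",
    "rosmarinic_acid",
    "salvianolic_acid_b",
    "soluble_solid",
)

AXIS_START = 176.0
AXIS_RESOLUTION = 2.83
AXIS_END = 3500.0


def default_axis(resolution: float = AXIS_RESOLUTION,
                 start: float = AXIS_START, end: float = AXIS_END) -> np.ndarray:
    """Instrument wavenumber grid; last point does not exceed ``end``."""
    n = int(math.floor((end - start) / resolution)) + 1
    return start + resolution * np.arange(n)


# ---------------------------------------------------------------------------
# gravimetric soluble-solid arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolubleSolidMeasurement:
    """Oven-drying weighing triplet: aliquot mass W, empty bottle W1, bottle+residue W2."""

    W: float
    W1: float
    W2: float


def compute_soluble_solid(m: SolubleSolidMeasurement) -> float:
    """Soluble-solid content Sc = (W2 - W1) / W * 100, in percent."""
    if not m.W > 0:
        raise InvalidMeasurementError(f"aliquot mass W must be positive, got {m.W}")
    if m.W2 < m.W1:
        raise InvalidMeasurementError(
            f"dried mass W2 ({m.W2}) below empty-bottle mass W1 ({m.W1})"
        )
    return (m.W2 - m.W1) / m.W * 100.0


# ---------------------------------------------------------------------------
# pure components
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PureComponentSpectrum:
    """Band profile of one mixture component: a sum of pseudo-Voigt peaks.

    ``eta`` is the Lorentzian fraction (0 = pure Gaussian, the default).
    """

    component_name: str
    peak_centers: tuple[float, ...]
    peak_widths: tuple[float, ...]
    peak_heights: tuple[float, ...]
    eta: float = 0.0

    def __post_init__(self):
        k = len(self.peak_centers)
        if len(self.peak_widths) != k or len(self.peak_heights) != k:
            raise ConfigurationError(
                f"{self.component_name}: centers/widths/heights length mismatch"
            )
        if any(w <= 0 for w in self.peak_widths):
            raise ConfigurationError(f"{self.component_name}: peak widths must be > 0")
        if any(h < 0 for h in self.peak_heights):
            raise ConfigurationError(f"{self.component_name}: peak heights must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigurationError(f"{self.component_name}: eta must lie in [0, 1]")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        lo, hi = axis[0], axis[-1]
        out = np.zeros_like(axis)
        for c, w, h in zip(self.peak_centers, self.peak_widths, self.peak_heights):
            if not lo <= c <= hi:
                raise ConfigurationError(
                    f"{self.component_name}: peak center {c} outside axis [{lo}, {hi}]"
                )
            gauss = np.exp(-0.5 * ((axis - c) / w) ** 2)
            lorentz = 1.0 / (1.0 + ((axis - c) / w) ** 2)
            out += h * ((1.0 - self.eta) * gauss + self.eta * lorentz)
        return out


#: Name of the constant-concentration solvent component (not an attribute).
SOLVENT = "water"


def default_components() -> list[PureComponentSpectrum]:
    """Component profiles: five analyte/matrix profiles plus the solvent.

    The dominant process bands sit near 1000, 1250 and 1500 cm^-1; peak
    heights are scaled roughly inversely to each component's concentration
    range so every analyte contributes comparable signal.  The water
    component carries the strong, nearly constant O-H bands (1640 and
    ~3250 cm^-1) that dominate aqueous-extract spectra; because it tops
    every spectrum, per-spectrum min-max scaling divides by a nearly
    constant range and analyte bands stay close to linear in concentration.
    """
    return [
        PureComponentSpectrum("danshensu",
                              (1000.0, 1283.0, 1605.0), (12.0, 15.0, 14.0),
                              (8e-3, 5e-3, 4e-3)),
        PureComponentSpectrum("ferulic_acid",
                              (1000.0, 1180.0, 1520.0), (11.0, 13.0, 16.0),
                              (6e-2, 9e-2, 7e-2)),
        PureComponentSpectrum("rosmarinic_acid",
                              (1250.0, 1340.0, 1605.0), (14.0, 12.0, 15.0),
                              (9e-3, 7e-3, 6e-3)),
        PureComponentSpectrum("salvianolic_acid_b",
                              (1250.0, 1450.0, 1710.0), (15.0, 13.0, 12.0),
                              (1.5e-3, 1.2e-3, 1.0e-3)),
        PureComponentSpectrum("soluble_solid",
                              (1000.0, 1500.0, 2900.0), (55.0, 70.0, 90.0),
                              (2.5e-4, 2.0e-4, 1.5e-4)),
        PureComponentSpectrum(SOLVENT,
                              (1640.0, 3250.0), (45.0, 130.0), (2.0, 6.0)),
    ]


# ---------------------------------------------------------------------------
# sampling schedule and kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingSchedule:
    """Dense-then-sparse sampling rule applied per reflux stage.

    Each stage of duration D is sampled every ``dense_interval`` minutes for
    the first ``dense_window`` minutes, then every ``sparse_interval`` until D.
    """

    stage_durations: tuple[float, ...] = (120.0, 90.0, 90.0)
    dense_interval: float = 5.0
    sparse_interval: float = 10.0
    dense_window: float = 60.0

    def __post_init__(self):
        if any(d <= 0 for d in self.stage_durations):
            raise ConfigurationError("stage durations must be positive")
        if self.dense_interval <= 0 or self.sparse_interval <= 0:
            raise ConfigurationError("sampling intervals must be positive")
        if self.dense_window < 0 or self.dense_window > max(self.stage_durations):
            raise ConfigurationError("dense_window outside the longest stage")


def schedule_timepoints(s: SamplingSchedule) -> list[tuple[int, float]]:
    """Sampling minutes per stage: (stage index starting at 1, minute in stage)."""
    points: list[tuple[int, float]] = []
    for stage, duration in enumerate(s.stage_durations, start=1):
        t = s.dense_interval
        prev = -np.inf
        while t <= min(s.dense_window, duration) + 1e-9:
            points.append((stage, round(t, 9)))
            prev = t
            t += s.dense_interval
        t = min(s.dense_window, duration) + s.sparse_interval
        while t <= duration + 1e-9:
            if t > prev:
                points.append((stage, round(t, 9)))
            t += s.sparse_interval
    for (s1, t1), (s2, t2) in zip(points, points[1:]):
        if s1 == s2 and t2 <= t1:
            raise ConfigurationError("schedule produced non-increasing time points")
    return points


@dataclass(frozen=True)
class ExtractionKinetics:
    """First-order saturating extraction per stage.

    The concentration trajectory within stage ``s`` (1-based) at minute ``t``
    is ``stage_resets[s-1] * (c_floor + (c_max - c_floor) * (1 - exp(-rate*t)))``
    -- non-decreasing in ``t`` and largest in stage 1, whose reset fraction
    defaults to 1.  ``c_floor`` models the solubles already mobilised at the
    first sampling point.
    """

    c_max: float
    rate: float
    stage_resets: tuple[float, ...] = (1.0, 0.4, 0.22)
    c_floor: float = 0.0

    def __post_init__(self):
        if self.c_max <= 0:
            raise ConfigurationError("c_max must be > 0")
        if self.rate <= 0:
            raise ConfigurationError("rate must be > 0")
        if any(r <= 0 for r in self.stage_resets):
            raise ConfigurationError("stage resets must be > 0")
        if not 0.0 <= self.c_floor < self.c_max:
            raise ConfigurationError("c_floor must lie in [0, c_max)")

    def concentration(self, stage: int, minute: float) -> float:
        reset = self.stage_resets[min(stage - 1, len(self.stage_resets) - 1)]
        g = 1.0 - math.exp(-self.rate * minute)
        return reset * (self.c_floor + (self.c_max - self.c_floor) * g)


def solve_kinetics_for_range(lo: float, hi: float, rate: float,
                             schedule: "SamplingSchedule | None" = None,
                             stage_resets: tuple[float, ...] = (1.0, 0.4, 0.22),
                             ) -> ExtractionKinetics:
    """Back-solve (c_floor, c_max) so the noise-free trajectory over the
    schedule attains exactly ``lo`` at its minimum and ``hi`` at its maximum.

    With value = reset * (c0*(1-g) + cm*g) and g increasing, the minimum sits
    at the smallest reset's first sampling point and the maximum at the
    largest reset's last point; the two conditions are linear in (c0, cm).
    """
    if not 0 < lo < hi:
        raise ConfigurationError("need 0 < lo < hi")
    schedule = schedule or SamplingSchedule()
    points = schedule_timepoints(schedule)
    g = {(s, t): 1.0 - math.exp(-rate * t) for s, t in points}
    reset = lambda s: stage_resets[min(s - 1, len(stage_resets) - 1)]
    coeffs = {(s, t): (reset(s) * (1.0 - g[s, t]), reset(s) * g[s, t])
              for s, t in points}
    # value = reset * (c0 + (cm - c0) * g) increases in both reset and g for
    # any 0 <= c0 < cm, so the extrema sit at (min reset, min g) / (max, max)
    lo_pt = min(points, key=lambda p: (reset(p[0]), g[p]))
    hi_pt = max(points, key=lambda p: (reset(p[0]), g[p]))
    A = np.array([coeffs[lo_pt], coeffs[hi_pt]])
    c0, cm = np.linalg.solve(A, np.array([lo, hi]))
    if not 0.0 <= c0 < cm:
        raise ConfigurationError(
            f"range ({lo}, {hi}) unreachable with rate={rate}, resets={stage_resets}"
        )
    return ExtractionKinetics(float(cm), rate, stage_resets, float(c0))


def default_kinetics() -> dict[str, ExtractionKinetics]:
    """Saturation kinetics (ug/mL) per attribute over the default schedule.

    Soluble solid is solved to span 418.7-4882.7 ug/mL before batch noise;
    the four analytes use plausible plateaus with moderate floors.
    """
    # per-analyte rates and stage resets differ so the mixture composition
    # (the only thing surviving per-spectrum normalisation) evolves over
    # time and stages, keeping the attributes identifiable from shape
    return {
        "danshensu": ExtractionKinetics(160.0, 0.040, (1.0, 0.50, 0.30), 40.0),
        "ferulic_acid": ExtractionKinetics(17.0, 0.010, (1.0, 0.25, 0.10), 4.0),
        "rosmarinic_acid": ExtractionKinetics(130.0, 0.025, (1.0, 0.45, 0.15), 30.0),
        "salvianolic_acid_b": ExtractionKinetics(950.0, 0.018, (1.0, 0.35, 0.28), 220.0),
        "soluble_solid": solve_kinetics_for_range(418.7, 4882.7, rate=0.015),
    }


DEFAULT_KINETICS = default_kinetics()


@dataclass(frozen=True)
class OutlierSpec:
    """Gross-outlier contamination: amplitude scaling plus random spikes.

    Spike channels are drawn once per contaminated sample (all replicates
    share them, so they survive replicate averaging) and each spike adds
    ``spike_scale x`` the spectrum's own maximum, so the distortion remains
    gross after any per-spectrum normalisation.
    """

    count: int = 5
    amplitude_factor: float = 10.0
    n_spikes: int = 3
    spike_scale: float = 5.0

    def __post_init__(self):
        if self.count < 0:
            raise ConfigurationError("outlier count must be >= 0")


@dataclass
class GeneratorConfig:
    n_batches: int = 7
    schedule: SamplingSchedule = field(default_factory=SamplingSchedule)
    kinetics: Mapping[str, ExtractionKinetics] = field(
        default_factory=lambda: dict(DEFAULT_KINETICS))
    components: Sequence[PureComponentSpectrum] = field(default_factory=default_components)
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    replicates: int = 3
    drop_last: bool = True
    axis_resolution: float = AXIS_RESOLUTION
    baseline_scale: float = 0.2
    noise_sd: float = 0.005
    batch_cv: float = 0.03          # lot-to-lot variation of kinetic plateaus
    reference_cv: float = 0.01      # HPLC / oven-drying measurement error
    timepoint_jitter_cv: float = 0.05
    # batch-specific interference: peaks at random positions whose amplitude
    # is unrelated to any analyte (matrix turbidity, window fouling, ...);
    # off by default, enabled in the end-to-end study config
    interferent_peaks: int = 6
    interferent_scale: float = 0.0
    solvent_cv: float = 0.01        # relative spread of the water bands

    def __post_init__(self):
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        missing = [a for a in ATTRIBUTES if a not in self.kinetics]
        if missing:
            raise ConfigurationError(f"kinetics missing for attributes: {missing}")


@dataclass
class SyntheticDataset:
    spectra: SpectraMatrix          # raw replicate acquisitions
    references: ReferenceTable      # per-sample (not per-replicate) values
    outlier_ids: list[str]
    seed: int
    truth: dict = field(default_factory=dict)  # noise-free concentrations


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_spectrum(concentrations: Sequence[float],
                    components: Sequence[PureComponentSpectrum],
                    axis: np.ndarray,
                    baseline_coeffs: Sequence[float] = (),
                    noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Linear mixture + smooth baseline + i.i.d. Gaussian noise.

    ``baseline_coeffs`` (b0, b1, b2) parameterise a broad decaying baseline
    ``b0*exp(-(v - v0)/1500) + b1*u + b2*u^2`` with ``u`` the axis scaled to
    [0, 1] -- a stand-in for fluorescence background.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if concentrations.size != len(components):
        raise DomainError(
            f"got {concentrations.size} concentrations for {len(components)} components"
        )
    if np.any(concentrations < 0):
        raise DomainError("concentrations must be non-negative")
    axis = np.asarray(axis, dtype=float)
    out = np.zeros_like(axis)
    for c, comp in zip(concentrations, components):
        if c != 0.0:
            out += c * comp.evaluate(axis)
    if len(baseline_coeffs):
        b = np.asarray(baseline_coeffs, dtype=float)
        u = (axis - axis[0]) / (axis[-1] - axis[0])
        baseline = b[0] * np.exp(-(axis - axis[0]) / 1500.0)
        if b.size > 1:
            baseline = baseline + b[1] * u
        if b.size > 2:
            baseline = baseline + b[2] * u ** 2
        out = out + baseline
    if noise_sd > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        out = out + rng.normal(0.0, noise_sd, size=axis.size)
    if not np.all(np.isfinite(out)):
        raise DomainError("rendered spectrum contains non-finite values")
    return out


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig | None = None, *,
                     seed: int = 0) -> SyntheticDataset:
    """Full synthetic campaign: batches x schedule x replicates.

    Sample ids follow the plant convention ``<batch>-<stage>-<index>``;
    replicate acquisitions append ``#<r>``.  Outliers are planted on whole
    samples (all replicates) so they survive replicate averaging.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    axis = default_axis(cfg.axis_resolution)
    points = schedule_timepoints(cfg.schedule)
    comp_names = [c.component_name for c in cfg.components]
    profiles = np.vstack([c.evaluate(axis) for c in cfg.components])

    sample_ids: list[str] = []
    true_conc: dict[str, dict[str, float]] = {}
    interferent_profile: dict[str, np.ndarray] = {}
    batch_of: dict[str, str] = {}
    for b in range(1, cfg.n_batches + 1):
        batch_factor = {a: max(0.05, 1.0 + cfg.batch_cv * rng.standard_normal())
                        for a in ATTRIBUTES}
        if cfg.interferent_peaks > 0 and cfg.interferent_scale > 0:
            centers = rng.uniform(axis[0] + 30, axis[-1] - 30,
                                  size=cfg.interferent_peaks)
            widths = rng.uniform(8.0, 40.0, size=cfg.interferent_peaks)
            heights = rng.uniform(0.3, 1.0, size=cfg.interferent_peaks)
            prof = np.zeros_like(axis)
            for c, w, h in zip(centers, widths, heights):
                prof += h * np.exp(-0.5 * ((axis - c) / w) ** 2)
            interferent_profile[str(b)] = prof
        else:
            interferent_profile[str(b)] = np.zeros_like(axis)
        stage_counter: dict[int, int] = {}
        for stage, minute in points:
            stage_counter[stage] = stage_counter.get(stage, 0) + 1
            sid = f"{b}-{stage}-{stage_counter[stage]}"
            jitter = {a: max(0.05, 1.0 + cfg.timepoint_jitter_cv * rng.standard_normal())
                      for a in ATTRIBUTES}
            conc = {a: cfg.kinetics[a].concentration(stage, minute)
                    * batch_factor[a] * jitter[a] for a in ATTRIBUTES}
            for name in comp_names:
                if name not in ATTRIBUTES:  # solvent-like constant components
                    conc[name] = max(0.0, 1.0 + cfg.solvent_cv
                                     * rng.standard_normal())
            sample_ids.append(sid)
            true_conc[sid] = conc
            batch_of[sid] = str(b)

    if cfg.drop_last:
        dropped = sample_ids.pop()
        true_conc.pop(dropped)

    n_samples = len(sample_ids)
    if cfg.outliers.count >= n_samples:
        raise ConfigurationError(
            f"outlier count ({cfg.outliers.count}) must be < sample count ({n_samples})"
        )
    outlier_idx = sorted(rng.choice(n_samples, size=cfg.outliers.count, replace=False))
    outlier_ids = [sample_ids[i] for i in outlier_idx]

    rows, row_ids = [], []
    replicate_of: dict[str, str] = {}
    for sid in sample_ids:
        conc_vec = np.array([true_conc[sid].get(name, 0.0) for name in comp_names])
        base = profiles.T @ conc_vec
        is_outlier = sid in outlier_ids
        spikes = (rng.choice(axis.size, size=cfg.outliers.n_spikes, replace=False)
                  if is_outlier and cfg.outliers.n_spikes else None)
        for r in range(1, cfg.replicates + 1):
            b0 = cfg.baseline_scale * (1.0 + 0.03 * rng.standard_normal())
            b1 = 0.05 * cfg.baseline_scale * rng.standard_normal()
            u = (axis - axis[0]) / (axis[-1] - axis[0])
            baseline = abs(b0) * np.exp(-(axis - axis[0]) / 1500.0) + b1 * u
            interf = (cfg.interferent_scale * rng.random()
                      * interferent_profile[batch_of[sid]])
            y = (base + baseline + interf
                 + rng.normal(0.0, cfg.noise_sd, size=axis.size))
            if is_outlier:
                y = y * cfg.outliers.amplitude_factor
                if spikes is not None:
                    y[spikes] += (cfg.outliers.spike_scale * np.max(np.abs(y))
                                  * (1.0 + rng.random(spikes.size)))
            rid = f"{sid}#{r}" if cfg.replicates > 1 else sid
            rows.append(y)
            row_ids.append(rid)
            replicate_of[rid] = sid

    spectra = SpectraMatrix(
        axis, np.vstack(rows), row_ids,
        meta={"replicate_of": replicate_of, "seed": seed,
              "replicates": cfg.replicates},
    )

    ref_rows = {}
    for sid in sample_ids:
        noisy = {a: true_conc[sid][a]
                 * max(0.0, 1.0 + cfg.reference_cv * rng.standard_normal())
                 for a in ATTRIBUTES}
        ref_rows[sid] = noisy
    references = ReferenceTable.from_dict(ref_rows, units="ug/mL")

    return SyntheticDataset(
        spectra=spectra,
        references=references,
        outlier_ids=outlier_ids,
        seed=seed,
        truth={"concentrations": true_conc},
    )


def write_dataset(ds: SyntheticDataset, directory: str | Path) -> dict[str, str]:
    """Write spectra CSV, reference CSV and a ground-truth sidecar JSON."""
    from .spectra import write_spectra_csv

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spectra_path = directory / "spectra.csv"
    refs_path = directory / "references.csv"
    sidecar_path = directory / "truth.json"
    write_spectra_csv(ds.spectra, spectra_path)
    ds.references.to_csv(refs_path)
    sidecar = {
        "seed": ds.seed,
        "outlier_ids": ds.outlier_ids,
        "replicate_of": ds.spectra.meta.get("replicate_of", {}),
        "true_concentrations": ds.truth.get("concentrations", {}),
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return {"spectra": str(spectra_path), "references": str(refs_path),
            "truth": str(sidecar_path)}
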