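"""Virtual endoscope: the synthetic stand-in for the physical bench.

Renders test patterns as seen through a parameterized endoscope, simulates
photocell transmission readings, ages endoscopes over sterilization cycles,
applies repairs, and generates whole fleet histories for the longitudinal
analyses.

Image formation applies a fixed, documented stage order:

    field mask -> Gaussian blur -> veiling glare -> vignetting -> dust
    -> additive sensor noise -> clip and quantize to 8 bit

The degradation model is deliberately simple: fibre transmission decays
multiplicatively per sterilization cycle, blur and veiling glare grow
additively. Absolute rates are illustrative, not clinical estimates.
"""

from __future__ import annotations

import enum
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from . import metrics
from .errors import InvalidArgumentError, ValidationError
from .patterns import TestPattern, default_pattern_suite
from .registry import Context, MeasurementRecord, Metric

__all__ = [
    "DustSpeck",
    "DegradationRates",
    "EndoscopeState",
    "PhotocellReading",
    "Repair",
    "FleetHistoryConfig",
    "FleetHistory",
    "render_through_endoscope",
    "simulate_transmission_measurement",
    "age_endoscope",
    "repair_endoscope",
    "simulate_fleet_history",
]

#: nominal photocell signal with the source directly on the cell, in volts
NOMINAL_SOURCE_SIGNAL = 2.5


@dataclass(frozen=True)
class DustSpeck:
    center: tuple[float, float]  # (row, col) in pixels
    radius_px: float
    opacity: float  # 0 = invisible, 1 = fully dark

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValidationError("dust radius must be > 0")
        if not 0 <= self.opacity <= 1:
            raise ValidationError(f"dust opacity must be in [0, 1], got {self.opacity}")


@dataclass(frozen=True)
class DegradationRates:
    """Per-sterilization-cycle change: multiplicative fibre decay,
    additive blur / veiling-glare growth."""

    fibre_decay: float = 0.0
    blur_growth: float = 0.0
    glare_growth: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.fibre_decay < 1:
            raise ValidationError("fibre_decay must be in [0, 1)")
        if self.blur_growth < 0 or self.glare_growth < 0:
            raise ValidationError("growth rates must be >= 0")


@dataclass(frozen=True)
class EndoscopeState:
    """Ground-truth optical condition of one virtual endoscope."""

    serial: str
    type_id: str
    blur_sigma: float = 0.0
    veiling_glare: float = 0.0
    vignetting: float = 0.0
    dust: tuple[DustSpeck, ...] = ()
    fibre_transmission: float = 1.0
    moisture: bool = False
    rates: DegradationRates = field(default_factory=DegradationRates)
    # factory values anchor the repair mapping
    factory_blur_sigma: float = 0.0
    factory_veiling_glare: float = 0.0
    factory_vignetting: float = 0.0
    factory_fibre_transmission: float = 1.0

    def __post_init__(self) -> None:
        if self.blur_sigma < 0:
            raise ValidationError("blur_sigma must be >= 0")
        for name in ("veiling_glare", "vignetting", "fibre_transmission"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        object.__setattr__(self, "dust", tuple(self.dust))

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["dust"] = [
            {"center": list(s.center), "radius_px": s.radius_px, "opacity": s.opacity}
            for s in self.dust
        ]
        d["rates"] = asdict(self.rates)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "EndoscopeState":
        d = dict(d)
        d["dust"] = tuple(
            DustSpeck(tuple(s["center"]), s["radius_px"], s["opacity"])
            for s in d.get("dust", ())
        )
        d["rates"] = DegradationRates(**d.get("rates", {}))
        return cls(**d)


@dataclass(frozen=True)
class PhotocellReading:
    """One transmission measurement: calibration and through-scope signals."""

    calibration_signal: float
    endoscope_signal: float
    noise_sd: float = 0.0

    def to_json_dict(self) -> dict:
        return asdict(self)


class Repair(str, enum.Enum):
    CLEAN_DUST = "CLEAN_DUST"
    REPLACE_ROD_LENS = "REPLACE_ROD_LENS"
    REPLACE_SAPPHIRE_WINDOW = "REPLACE_SAPPHIRE_WINDOW"
    REPLACE_OBJECTIVE = "REPLACE_OBJECTIVE"
    FIX_MOISTURE = "FIX_MOISTURE"
    REFIT_EYEPIECE = "REFIT_EYEPIECE"
    REPLACE_FIBRES = "REPLACE_FIBRES"


# ---------------------------------------------------------------------------
# image formation
# ---------------------------------------------------------------------------


def _field_geometry(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, float]:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.ogrid[:h, :w]
    r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    r_max = min(h, w) / 2.0
    return r, np.broadcast_to(r <= r_max, shape), r_max


def render_through_endoscope(
    pattern: TestPattern | np.ndarray,
    state: EndoscopeState,
    seed: int | None = None,
    noise_sd: float = 0.0,
    sensor_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Capture of *pattern* through the virtual endoscope, as uint8."""
    pixels = pattern.pixels if isinstance(pattern, TestPattern) else np.asarray(pattern)
    if pixels.ndim != 2:
        raise InvalidArgumentError("pattern must be a 2-D image")
    if sensor_shape is not None and tuple(pixels.shape) != tuple(sensor_shape):
        raise InvalidArgumentError(
            f"pattern shape {pixels.shape} does not match sensor {sensor_shape}"
        )
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")

    img = pixels.astype(float)
    r, mask, r_max = _field_geometry(img.shape)

    # (1) circular field mask
    img = np.where(mask, img, 0.0)
    # (2) point-spread blur
    if state.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, state.blur_sigma)
    # (3) veiling glare toward the masked-field mean
    if state.veiling_glare > 0:
        h = state.veiling_glare
        field_mean = img[mask].mean()
        img = np.where(mask, (1.0 - h) * img + h * field_mean, img)
    # (4) radial vignetting
    if state.vignetting > 0:
        img = img * (1.0 - state.vignetting * (r / r_max) ** 2)
    # (5) dust as multiplicative dark discs
    for speck in state.dust:
        sy, sx = speck.center
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        inside = (yy - sy) ** 2 + (xx - sx) ** 2 <= speck.radius_px**2
        img = np.where(inside, img * (1.0 - speck.opacity), img)
    # (6) sensor noise
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    # (7) clip and quantize
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def simulate_transmission_measurement(
    state: EndoscopeState,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> PhotocellReading:
    """Photocell pair: calibration at the nominal source level, endoscope
    signal scaled by fibre transmission with seeded relative noise."""
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    calibration = NOMINAL_SOURCE_SIGNAL
    signal = calibration * state.fibre_transmission
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal *= 1.0 + rng.normal(0.0, noise_sd)
    return PhotocellReading(
        calibration_signal=calibration,
        endoscope_signal=max(0.0, signal),
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# aging and repair
# ---------------------------------------------------------------------------


def age_endoscope(state: EndoscopeState, n_cycles: int) -> EndoscopeState:
    """State after *n_cycles* sterilization cycles; the input is not mutated.

    Compositional: ``age(age(s, a), b) == age(s, a + b)``.
    """
    if n_cycles < 0:
        raise InvalidArgumentError(f"n_cycles must be >= 0, got {n_cycles}")
    r = state.rates
    return replace(
        state,
        fibre_transmission=state.fibre_transmission * (1.0 - r.fibre_decay) ** n_cycles,
        blur_sigma=state.blur_sigma + n_cycles * r.blur_growth,
        veiling_glare=min(1.0, state.veiling_glare + n_cycles * r.glare_growth),
    )


def _restored(factory: float, fraction: float, *, higher_is_better: bool) -> float:
    """Repair mapping: restore a parameter toward its factory value.

    ``fraction`` in (0, 1]; 1.0 restores exactly to factory. Parameters where
    lower is better come back slightly above factory (factory / fraction),
    parameters where higher is better slightly below (factory * fraction).
    """
    if higher_is_better:
        return factory * fraction
    return factory / fraction


def repair_endoscope(
    state: EndoscopeState,
    repairs: Iterable[Repair],
    restore_fraction: float | None = None,
    seed: int | None = None,
    restore_range: tuple[float, float] = (0.9, 1.0),
) -> EndoscopeState:
    """Apply a set of repairs, each resetting its parameters toward factory.

    Mapping (f = restore fraction, drawn per repair from ``restore_range``
    unless ``restore_fraction`` pins it):

    ==========================  =============================================
    CLEAN_DUST                  dust list emptied
    REPLACE_ROD_LENS            blur_sigma <- factory_blur_sigma / f
    REPLACE_OBJECTIVE           blur_sigma <- factory_blur_sigma / f,
                                vignetting <- min(1, factory_vignetting / f)
    REPLACE_SAPPHIRE_WINDOW     veiling_glare <- min(1, factory_veiling_glare / f)
    FIX_MOISTURE                moisture <- False
    REFIT_EYEPIECE              vignetting <- min(1, factory_vignetting / f)
    REPLACE_FIBRES              fibre_transmission <- factory_fibre_transmission * f
    ==========================  =============================================
    """
    repairs = {Repair(r) for r in repairs}
    if not repairs:
        raise InvalidArgumentError("repair set must be non-empty")
    rng = np.random.default_rng(seed)

    def frac() -> float:
        if restore_fraction is not None:
            return float(restore_fraction)
        lo, hi = restore_range
        return float(rng.uniform(lo, hi))

    updates: dict = {}
    # iterate in enum order so seeded draws are deterministic
    for repair in sorted(repairs, key=lambda r: r.value):
        f = frac()
        if repair is Repair.CLEAN_DUST:
            updates["dust"] = ()
        elif repair is Repair.REPLACE_ROD_LENS:
            updates["blur_sigma"] = _restored(
                state.factory_blur_sigma, f, higher_is_better=False
            )
        elif repair is Repair.REPLACE_OBJECTIVE:
            updates["blur_sigma"] = _restored(
                state.factory_blur_sigma, f, higher_is_better=False
            )
            updates["vignetting"] = min(
                1.0, _restored(state.factory_vignetting, f, higher_is_better=False)
            )
        elif repair is Repair.REPLACE_SAPPHIRE_WINDOW:
            updates["veiling_glare"] = min(
                1.0, _restored(state.factory_veiling_glare, f, higher_is_better=False)
            )
        elif repair is Repair.FIX_MOISTURE:
            updates["moisture"] = False
        elif repair is Repair.REFIT_EYEPIECE:
            updates["vignetting"] = min(
                1.0, _restored(state.factory_vignetting, f, higher_is_better=False)
            )
        elif repair is Repair.REPLACE_FIBRES:
            updates["fibre_transmission"] = min(
                1.0,
                _restored(state.factory_fibre_transmission, f, higher_is_better=True),
            )
    return replace(state, **updates)


#: repairs applied by the fleet simulator when a metric triggers rejection
_TRIGGERED_REPAIRS = {
    Metric.TRANSMISSION: frozenset({Repair.REPLACE_FIBRES}),
    Metric.CONTRAST: frozenset(
        {Repair.CLEAN_DUST, Repair.REPLACE_ROD_LENS, Repair.REPLACE_SAPPHIRE_WINDOW}
    ),
}


# ---------------------------------------------------------------------------
# fleet history
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FleetHistoryConfig:
    """Parameters of the synthetic measurement-period simulation."""

    n_types: int = 2
    endoscopes_per_type: int = 3
    n_sessions: int = 20
    session_interval_days: float = 3.5
    image_size: int = 256
    #: relative sd of the photocell signal (applies to every reading)
    photocell_noise_sd: float = 0.005
    #: additive camera noise, grey levels
    sensor_noise_sd: float = 1.0
    #: sterilization cycles between consecutive sessions
    cycles_per_session: int = 4
    initial_transmission_range: tuple[float, float] = (0.65, 0.95)
    initial_blur_range: tuple[float, float] = (0.2, 1.0)
    initial_glare_range: tuple[float, float] = (0.0, 0.08)
    fibre_decay_range: tuple[float, float] = (0.0005, 0.006)
    blur_growth_range: tuple[float, float] = (0.002, 0.02)
    glare_growth_range: tuple[float, float] = (0.0, 0.004)
    #: when True, endoscopes whose metric drops below ``repair_fraction`` of
    #: the running best-of-type are repaired before the next session
    repair_enabled: bool = True
    repair_fraction: float = 0.20
    restore_range: tuple[float, float] = (0.9, 1.0)
    start: datetime = datetime(2021, 7, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_types", "endoscopes_per_type", "n_sessions"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.session_interval_days <= 0:
            raise ValidationError("session_interval_days must be > 0")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["start"] = self.start.isoformat()
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "FleetHistoryConfig":
        d = dict(d)
        if "start" in d:
            d["start"] = datetime.fromisoformat(d["start"])
        for key in (
            "initial_transmission_range",
            "initial_blur_range",
            "initial_glare_range",
            "fibre_decay_range",
            "blur_growth_range",
            "glare_growth_range",
            "restore_range",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


REFERENCE_SERIAL = "REF-0001"
REFERENCE_TYPE = "REFERENCE"


@dataclass
class FleetHistory:
    """Simulated measurement period: records plus ground-truth states."""

    config: FleetHistoryConfig
    records: list[MeasurementRecord]
    #: ground truth per (serial, session index), captured at measurement time
    states: dict[tuple[str, int], EndoscopeState]
    repairs: list[tuple[str, int, tuple[str, ...]]]  # (serial, session, repair names)

    def records_for(self, serial: str) -> list[MeasurementRecord]:
        return [r for r in self.records if r.serial == serial]

    def ground_truth_series(self, serial: str, field_name: str) -> list[float]:
        sessions = sorted(s for (ser, s) in self.states if ser == serial)
        return [getattr(self.states[(serial, s)], field_name) for s in sessions]

    def export_records_csv(self, path: str | Path) -> int:
        import csv

        from .registry import CSV_HEADER

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for rec in self.records:
                writer.writerow(rec.to_row())
        return len(self.records)

    def export_ground_truth_csv(self, path: str | Path) -> int:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["serial", "session", "fibre_transmission", "blur_sigma",
                 "veiling_glare", "vignetting", "moisture"]
            )
            n = 0
            for (serial, session), st in sorted(self.states.items()):
                writer.writerow(
                    [serial, session, repr(st.fibre_transmission),
                     repr(st.blur_sigma), repr(st.veiling_glare),
                     repr(st.vignetting), int(st.moisture)]
                )
                n += 1
        return n


def _initial_state(
    serial: str, type_id: str, rng: np.random.Generator, cfg: FleetHistoryConfig
) -> EndoscopeState:
    transmission = rng.uniform(*cfg.initial_transmission_range)
    blur = rng.uniform(*cfg.initial_blur_range)
    glare = rng.uniform(*cfg.initial_glare_range)
    rates = DegradationRates(
        fibre_decay=rng.uniform(*cfg.fibre_decay_range),
        blur_growth=rng.uniform(*cfg.blur_growth_range),
        glare_growth=rng.uniform(*cfg.glare_growth_range),
    )
    return EndoscopeState(
        serial=serial,
        type_id=type_id,
        blur_sigma=blur,
        veiling_glare=glare,
        fibre_transmission=transmission,
        rates=rates,
        factory_blur_sigma=blur,
        factory_veiling_glare=glare,
        factory_fibre_transmission=transmission,
    )


def _measure(
    state: EndoscopeState,
    suite: Sequence[TestPattern],
    timestamp: datetime,
    context: Context,
    rng: np.random.Generator,
    cfg: FleetHistoryConfig,
) -> MeasurementRecord:
    line_patterns, roi_pattern = suite[:-1], suite[-1]
    captures = [
        render_through_endoscope(
            p, state, seed=int(rng.integers(2**31)), noise_sd=cfg.sensor_noise_sd
        )
        for p in line_patterns
    ]
    roi_capture = render_through_endoscope(
        roi_pattern, state, seed=int(rng.integers(2**31)), noise_sd=cfg.sensor_noise_sd
    )
    reading = simulate_transmission_measurement(
        state, seed=int(rng.integers(2**31)), noise_sd=cfg.photocell_noise_sd
    )
    return metrics.measure_endoscope(
        captures,
        roi_capture,
        reading,
        moisture_observed=state.moisture,
        serial=state.serial,
        type_id=state.type_id,
        timestamp=timestamp,
        context=context,
    )


def simulate_fleet_history(config: FleetHistoryConfig) -> FleetHistory:
    """Simulate the whole measurement period.

    One reference endoscope with zero degradation rates is measured every
    session; clinical endoscopes are measured, aged between sessions, and —
    when a metric falls below ``repair_fraction`` of the running
    best-of-type — sent for repair (their failing session is tagged
    BEFORE_REPAIR, the following one AFTER_REPAIR). Deterministic for a
    fixed seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    suite = default_pattern_suite(cfg.image_size)

    reference = EndoscopeState(
        serial=REFERENCE_SERIAL,
        type_id=REFERENCE_TYPE,
        blur_sigma=0.5,
        fibre_transmission=0.9,
        factory_blur_sigma=0.5,
        factory_fibre_transmission=0.9,
    )
    fleet: list[EndoscopeState] = []
    for t in range(cfg.n_types):
        type_id = f"TYPE-{t:02d}"
        for e in range(cfg.endoscopes_per_type):
            serial = f"{type_id}-SN{e:03d}"
            fleet.append(_initial_state(serial, type_id, rng, cfg))

    best: dict[tuple[str, Metric], float] = {}
    pending_repair: dict[str, frozenset[Repair]] = {}
    just_repaired: set[str] = set()
    records: list[MeasurementRecord] = []
    states: dict[tuple[str, int], EndoscopeState] = {}
    repair_log: list[tuple[str, int, tuple[str, ...]]] = []

    for session in range(cfg.n_sessions):
        timestamp = cfg.start + timedelta(days=session * cfg.session_interval_days)

        states[(REFERENCE_SERIAL, session)] = reference
        records.append(
            _measure(reference, suite, timestamp, Context.REFERENCE, rng, cfg)
        )

        next_fleet: list[EndoscopeState] = []
        for state in fleet:
            if session == 0:
                context = Context.NEW
            elif state.serial in just_repaired:
                context = Context.AFTER_REPAIR
            else:
                context = Context.CLINICAL
            states[(state.serial, session)] = state
            record = _measure(state, suite, timestamp, context, rng, cfg)

            # decide repairs against the running best-of-type
            triggered: set[Repair] = set()
            if cfg.repair_enabled and context is Context.CLINICAL:
                for metric in Metric:
                    key = (state.type_id, metric)
                    b = best.get(key)
                    if b and b > 0 and record.value(metric) / b < cfg.repair_fraction:
                        triggered |= _TRIGGERED_REPAIRS[metric]
            if triggered:
                record = replace(record, context=Context.BEFORE_REPAIR)
                pending_repair[state.serial] = frozenset(triggered)

            records.append(record)
            for metric in Metric:
                key = (state.type_id, metric)
                best[key] = max(best.get(key, 0.0), record.value(metric))

            # evolve to the next session
            aged = age_endoscope(state, cfg.cycles_per_session)
            if state.serial in pending_repair:
                repairs = pending_repair.pop(state.serial)
                aged = repair_endoscope(
                    aged,
                    repairs,
                    seed=int(rng.integers(2**31)),
                    restore_range=cfg.restore_range,
                )
                repair_log.append(
                    (state.serial, session, tuple(sorted(r.value for r in repairs)))
                )
                just_repaired.add(state.serial)
            else:
                just_repaired.discard(state.serial)
            next_fleet.append(aged)
        fleet = next_fleet

    return FleetHistory(
        config=cfg, records=records, states=states, repairs=repair_log
    )
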