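"""Instrument decibel scales, dynamic ranges and the plateau effect.

A perimetric threshold in dB expresses stimulus attenuation from an
instrument-specific maximum: ``stimulus_asb = 10 ** ((k - dB) / 10)``, so
0 dB is the brightest presentable stimulus (10,000 asb when k = 40; 1,000 asb
when k = 30) and larger dB means a dimmer stimulus.  Two instruments sharing
the same background differ only by their k constants, hence conversion is a
pure offset: 0 dB on the k = 30 scale is the same luminance as 10 dB on the
k = 40 scale.  Sensitivities below an instrument's floor are recorded at the
floor — the plateau that truncates deep defects on short-range instruments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "InstrumentModel",
    "HFA",
    "TWINFIELD2",
    "get_instrument",
    "luminance_from_db",
    "db_from_luminance",
    "convert_db",
    "clip_to_range",
    "asb_to_cdm2",
]


@dataclass(frozen=True)
class InstrumentModel:
    """A perimeter's dB scale and dynamic range.

    ``db_floor`` is the sensitivity recorded at maximum stimulus luminance
    (by convention 0 dB); ``db_ceiling`` is the dimmest presentable stimulus.
    """

    name: str
    k: float
    background_asb: float = 31.5
    db_floor: float = 0.0
    db_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.db_ceiling is None:
            # Dimmest stimulus defaults to 1 asb, i.e. dB = k.
            object.__setattr__(self, "db_ceiling", float(self.k))
        if self.db_ceiling <= self.db_floor:
            raise ValueError("db_ceiling must exceed db_floor")

    @property
    def max_stimulus_asb(self) -> float:
        return luminance_from_db(self.db_floor, self.k)

    @property
    def min_stimulus_asb(self) -> float:
        return luminance_from_db(self.db_ceiling, self.k)


HFA = InstrumentModel(name="HFA", k=40.0)
TWINFIELD2 = InstrumentModel(name="Twinfield2", k=30.0)

_BUILTINS = {m.name.lower(): m for m in (HFA, TWINFIELD2)}


def get_instrument(name: str) -> InstrumentModel:
    """Look up a built-in instrument by (case-insensitive) name."""
    try:
        return _BUILTINS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown instrument {name!r}; built-ins: "
            f"{sorted(m.name for m in _BUILTINS.values())}"
        ) from None


def luminance_from_db(db: float, k: float) -> float:
    """Stimulus luminance in asb for a threshold on the k-scale."""
    return 10.0 ** ((k - db) / 10.0)


def db_from_luminance(delta_l: float, k: float) -> float:
    """Inverse of :func:`luminance_from_db`."""
    if delta_l <= 0:
        raise ValueError(f"stimulus luminance must be positive, got {delta_l}")
    return k - 10.0 * math.log10(delta_l)


def convert_db(
    db: float, from_instrument: InstrumentModel, to_instrument: InstrumentModel
) -> float:
    """Re-express a threshold on another instrument's dB scale.

    The same physical stimulus luminance is preserved; with a shared
    background this reduces to an offset of ``k_to - k_from``.
    """
    if from_instrument.background_asb != to_instrument.background_asb:
        warnings.warn(
            "instruments have different background luminances; conversion is "
            "luminance-exact but contrasts differ",
            stacklevel=2,
        )
    return db + (to_instrument.k - from_instrument.k)


def clip_to_range(db: float, instrument: InstrumentModel) -> tuple[float, bool]:
    """Record a threshold within the instrument's dynamic range.

    Returns ``(recorded_db, saturated)``.  Values strictly below the floor are
    recorded at the floor (the plateau); values strictly above the ceiling at
    the ceiling.  Exact boundary values are in range and unflagged.
    """
    if db < instrument.db_floor:
        return instrument.db_floor, True
    if db > instrument.db_ceiling:
        return instrument.db_ceiling, True
    return float(db), False


def asb_to_cdm2(luminance: float) -> float:
    """Convert apostilb to cd/m^2 (divide by pi)."""
    if luminance < 0:
        raise ValueError(f"luminance must be non-negative, got {luminance}")
    return luminance / math.pi
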