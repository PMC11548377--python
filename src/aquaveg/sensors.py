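"""Sensor-specific constants for the spectral indices.

The aquatic vegetation index (AVI) is the negated tasseled-cap wetness
component, so it needs the six per-band wetness coefficients of the sensor
that acquired the scene; the floating algae index (FAI) needs the band-center
wavelengths of the red, NIR and SWIR1 bands.  Both sets of constants are
published, fixed properties of each instrument, collected here as frozen
profiles.

Coefficient provenance (reflectance-domain tasseled-cap wetness):

* ``TM``   — Crist (1985), Landsat 4/5 Thematic Mapper reflectance factors.
* ``ETM+`` — Huang et al. (2002), Landsat 7 at-satellite reflectance.
* ``OLI``  — Baig et al. (2014), Landsat 8 OLI.

Band order everywhere in this package is (blue, green, red, NIR, SWIR1,
SWIR2).  A custom coefficient set can be supplied through
:func:`register_profile` (for example to reproduce a DN-domain analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "BAND_NAMES",
    "SensorProfile",
    "get_profile",
    "register_profile",
    "supported_sensors",
]

BAND_NAMES = ("blue", "green", "red", "nir", "swir1", "swir2")


class UnknownSensorError(KeyError):
    """Raised when a sensor identifier has no registered profile."""


@dataclass(frozen=True)
class SensorProfile:
    """Immutable per-sensor constants.

    Parameters
    ----------
    sensor_id
        Short instrument name, e.g. ``"TM"``, ``"ETM+"`` or ``"OLI"``.
    wetness_coefficients
        The six tasseled-cap wetness coefficients, ordered
        (blue, green, red, NIR, SWIR1, SWIR2).  Both SWIR coefficients are
        negative in every published wetness set; this is validated.
    band_wavelengths_nm
        Band-center wavelengths in nanometres; must contain at least
        ``red``, ``nir`` and ``swir1`` (used by the FAI baseline).
    """

    sensor_id: str
    wetness_coefficients: tuple[float, ...]
    band_wavelengths_nm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.wetness_coefficients) != len(BAND_NAMES):
            raise ValueError(
                f"expected {len(BAND_NAMES)} wetness coefficients "
                f"(order {BAND_NAMES}), got {len(self.wetness_coefficients)}"
            )
        k_swir1 = self.wetness_coefficients[BAND_NAMES.index("swir1")]
        k_swir2 = self.wetness_coefficients[BAND_NAMES.index("swir2")]
        if k_swir1 >= 0 or k_swir2 >= 0:
            raise ValueError(
                "both SWIR wetness coefficients must be negative "
                f"(got swir1={k_swir1}, swir2={k_swir2}); not a wetness set?"
            )
        for band in ("red", "nir", "swir1"):
            if band not in self.band_wavelengths_nm:
                raise ValueError(f"band_wavelengths_nm must include {band!r}")
        lam = self.band_wavelengths_nm
        if not (lam["red"] < lam["nir"] < lam["swir1"]):
            raise ValueError(
                "band centers must satisfy red < nir < swir1, got "
                f"{lam['red']} / {lam['nir']} / {lam['swir1']} nm"
            )


_PROFILES: dict[str, SensorProfile] = {
    "TM": SensorProfile(
        sensor_id="TM",
        # Crist (1985) reflectance-factor wetness, TM bands 1-5,7
        wetness_coefficients=(0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109),
        band_wavelengths_nm={"red": 660.0, "nir": 830.0, "swir1": 1650.0},
    ),
    "ETM+": SensorProfile(
        sensor_id="ETM+",
        # Huang et al. (2002) at-satellite reflectance wetness
        wetness_coefficients=(0.2626, 0.2141, 0.0926, 0.0656, -0.7629, -0.5388),
        band_wavelengths_nm={"red": 660.0, "nir": 835.0, "swir1": 1650.0},
    ),
    "OLI": SensorProfile(
        sensor_id="OLI",
        # Baig et al. (2014) OLI wetness, bands 2-7
        wetness_coefficients=(0.1511, 0.1973, 0.3283, 0.3407, -0.7117, -0.4559),
        band_wavelengths_nm={"red": 655.0, "nir": 865.0, "swir1": 1609.0},
    ),
}


def supported_sensors() -> tuple[str, ...]:
    """Identifiers with a registered profile."""
    return tuple(sorted(_PROFILES))


def get_profile(sensor_id: str) -> SensorProfile:
    """Return the frozen :class:`SensorProfile` for ``sensor_id``.

    Raises
    ------
    UnknownSensorError
        If ``sensor_id`` is not registered; the message names the
        supported set.
    """
    try:
        return _PROFILES[sensor_id]
    except KeyError:
        raise UnknownSensorError(
            f"unknown sensor {sensor_id!r}; supported: {supported_sensors()}"
        ) from None


def register_profile(profile: SensorProfile, *, overwrite: bool = False) -> None:
    """Register a custom profile (e.g. an alternative wetness derivation).

    Overwriting a built-in requires ``overwrite=True`` so that accidental
    shadowing of the published constants is loud.
    """
    if profile.sensor_id in _PROFILES and not overwrite:
        raise ValueError(
            f"profile {profile.sensor_id!r} already registered; "
            "pass overwrite=True to replace it"
        )
    _PROFILES[profile.sensor_id] = profile
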