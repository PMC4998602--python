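"""Decibel <-> linear contrast-sensitivity conversion per perimetric modality.

Perimetric decibels are attenuation units: ``dB = k * log10(CS)`` with a
device-specific scale constant ``k``.  Humphrey SAP and SWAP use a Weber
increment scale (k = 10); the Matrix FDT reports contrast-amplitude decibels
on a Michelson scale (k = 20).  Because the percent-of-mean-normal scale is
a *ratio* of contrast sensitivities, the absolute luminance constants of each
device cancel exactly and only ``k`` matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MODALITIES",
    "ModalityScale",
    "get_scale",
    "db_to_cs",
    "cs_to_db",
    "percent_of_normal",
]

MODALITIES = ("SAP", "SWAP", "FDT")


@dataclass(frozen=True)
class ModalityScale:
    """Scale constants of one perimetric modality."""

    modality: str
    db_per_log10: float  # 10 for Weber (SAP/SWAP), 20 for Michelson (FDT)
    floor_db: float = 0.0  # device floor; printed "<0 dB" maps here


_SCALES: dict[str, ModalityScale] = {
    "SAP": ModalityScale("SAP", 10.0),
    "SWAP": ModalityScale("SWAP", 10.0),
    "FDT": ModalityScale("FDT", 20.0),
}


def get_scale(modality: str) -> ModalityScale:
    try:
        return _SCALES[modality]
    except KeyError:
        raise ValueError(
            f"unknown modality {modality!r}; expected one of {MODALITIES}"
        ) from None


def db_to_cs(db, modality: str):
    """Convert decibel sensitivity to unitless linear contrast sensitivity.

    Values below the device floor are clamped to the floor before conversion
    (the device cannot measure below it, and negative dB would explode the
    linear scale asymmetrically).
    """
    scale = get_scale(modality)
    db = np.maximum(np.asarray(db, dtype=float), scale.floor_db)
    return 10.0 ** (db / scale.db_per_log10)


def cs_to_db(cs, modality: str):
    """Inverse of :func:`db_to_cs` above the floor."""
    scale = get_scale(modality)
    return scale.db_per_log10 * np.log10(np.asarray(cs, dtype=float))


def percent_of_normal(db, normal_db, modality: str):
    """Sensitivity as percent of the age-matched mean normal at that location.

    ``100 * CS(db) / CS(normal_db)``; depends only on the dB difference, so
    omitting device luminance constants is exact.  Not capped at 100:
    supernormal values carry information for improvement flags.
    """
    return 100.0 * db_to_cs(db, modality) / db_to_cs(normal_db, modality)
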