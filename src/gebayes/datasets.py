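"""Packaged clinical survival datasets used in the worked examples.

``data1`` — survival of 16 cervical-cancer patients under radiotherapy
alone (the control arm of a randomised trial of a radiosensitiser), in
days from study entry; death from the cancer is the event.

``data2`` — survival of 121 breast-cancer patients treated 1929-1938, in
months; a large-sample example.

In both listings a trailing ``*`` marks a censored observation.  The
records are stored exactly as printed in the source listings, in the
original time units.
"""

from __future__ import annotations

import numpy as np

from .distribution import SurvivalSample

__all__ = ["load_fixture", "FIXTURE_NAMES"]

# cervical cancer, treatment A (radiotherapy alone), days
_DATA1 = (
    "90, 890*, 142, 1037, 150, 1090*, 269, 1113*, 291, 1153, 468*, 1297, "
    "680, 1429, 837, 1577*"
)

# breast cancer, months
_DATA2 = (
    "0.3, 0.3*, 4.0*, 5.0, 5.6, 6.2, 6.3, 6.6, 6.8, 7.4*, 7.5, 8.4, 8.4, "
    "10.3, 11.0, 11.8, 12.2, 12.3, 13.5, 14.4, 14.4, 14.8, 15.5*, 15.7, "
    "16.2, 16.3, 16.5, 16.8, 17.2, 17.3, 17.5, 17.9, 19.8, 20.4, 20.9, "
    "21.0, 21.0, 21.1, 23.0, 23.4*, 23.6, 24.0, 24.0, 27.9, 28.2, 29.1, "
    "30, 31, 31, 32, 35, 35, 37*, 37*, 37*, 38, 38*, 38*, 39*, 39*, 40, "
    "40*, 40*, 41, 41, 41*, 42, 43*, 43*, 43*, 44, 45*, 45*, 46*, 46*, "
    "47*, 48, 49*, 51, 51, 51*, 52, 54, 55*, 56, 57*, 58*, 59*, 60, 60*, "
    "60*, 61*, 62*, 65*, 65*, 67*, 67*, 68*, 69*, 78, 80, 83*, 88*, 89, "
    "90, 93*, 96*, 103*, 105*, 109*, 109*, 111*, 115*, 117*, 125*, 126, "
    "127*, 129*, 129*, 139*, 154*"
)

FIXTURE_NAMES = ("data1", "data2")


def _parse_starred(listing: str) -> SurvivalSample:
    times, events = [], []
    for token in listing.split(","):
        token = token.strip()
        if not token:
            continue
        censored = token.endswith("*")
        times.append(float(token.rstrip("*")))
        events.append(0 if censored else 1)
    return SurvivalSample(np.array(times), np.array(events))


def load_fixture(name: str) -> SurvivalSample:
    """Return one of the packaged datasets as a :class:`SurvivalSample`."""
    if name == "data1":
        return _parse_starred(_DATA1)
    if name == "data2":
        return _parse_starred(_DATA2)
    raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
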