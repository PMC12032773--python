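"""64-channel 10-20/10-10 montage: labels, 3-D positions, and the left/right mirror map.

The layout models a 64-channel cap recorded against an FCz reference with
mastoid channels TP9/TP10 available for offline re-referencing.  Electrode
positions come from MNE's standard 10-05 montage and are used for Gaussian
scalp weight maps (synthetic generator) and neighbor-based interpolation.
"""

from __future__ import annotations

import functools
import re

import numpy as np

# 6 midline + 29 left/right pairs = 64 channels. FCz is carried as a data
# channel (identically zero before re-referencing, recovered afterwards).
MIDLINE = ["Fz", "FCz", "Cz", "CPz", "Pz", "Oz"]
PAIRS = [
    ("Fp1", "Fp2"), ("AF7", "AF8"), ("AF3", "AF4"),
    ("F7", "F8"), ("F5", "F6"), ("F3", "F4"), ("F1", "F2"),
    ("FT9", "FT10"), ("FT7", "FT8"), ("FC5", "FC6"), ("FC3", "FC4"), ("FC1", "FC2"),
    ("T7", "T8"), ("C5", "C6"), ("C3", "C4"), ("C1", "C2"),
    ("TP9", "TP10"), ("TP7", "TP8"), ("CP5", "CP6"), ("CP3", "CP4"), ("CP1", "CP2"),
    ("P7", "P8"), ("P5", "P6"), ("P3", "P4"), ("P1", "P2"),
    ("PO9", "PO10"), ("PO7", "PO8"), ("PO3", "PO4"),
    ("O1", "O2"),
]

CHANNELS_64: list[str] = []
for _l, _r in PAIRS:
    CHANNELS_64 += [_l, _r]
CHANNELS_64 += MIDLINE

REFERENCE = "FCz"
MASTOIDS = ("TP9", "TP10")

#: the 21 channels used for CSP decoding
CSP_CHANNELS = [
    "F3", "F4", "C3", "C4", "P3", "P4", "Fz", "Cz", "Pz",
    "F1", "F2", "C1", "C2", "P1", "P2", "F5", "F6", "C5", "C6", "P5", "P6",
]

_NUM_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def mirror_label(label: str) -> str:
    """Homologous channel across the midline: odd<->even suffix, 'z' fixed."""
    if label.endswith("z") or label.endswith("Z"):
        return label
    m = _NUM_RE.match(label)
    if m is None:
        raise ValueError(f"channel {label!r} has no mirror partner and is not midline")
    stem, num = m.group(1), int(m.group(2))
    partner = num - 1 if num % 2 == 0 else num + 1
    return f"{stem}{partner}"


def mirror_map(labels: list[str] | None = None) -> dict[str, str]:
    """Mapping channel -> mirrored channel, validated against the label set."""
    labels = list(labels) if labels is not None else list(CHANNELS_64)
    out = {}
    lset = set(labels)
    for ch in labels:
        p = mirror_label(ch)
        if p not in lset:
            raise ValueError(f"mirror partner {p!r} of {ch!r} not in montage")
        out[ch] = p
    return out


@functools.lru_cache(maxsize=4)
def channel_positions(labels: tuple[str, ...] = tuple(CHANNELS_64)) -> np.ndarray:
    """(n, 3) electrode positions in meters (head frame)."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    return np.array([pos[ch] for ch in labels])


def gaussian_scalp_map(center: str, labels: list[str], sigma_m: float = 0.035) -> np.ndarray:
    """Gaussian spatial weight map on the scalp, 1.0 at the center electrode.

    sigma_m = 0.035 m keeps the weight at the homologous contralateral site and
    at the mastoids below 1e-3, so injected effects stay channel-local.
    """
    pos = channel_positions(tuple(labels))
    c = pos[labels.index(center)]
    d2 = np.sum((pos - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma_m**2))
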