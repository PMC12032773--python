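"""Minimal BrainVision writer (.vhdr/.vmrk/.eeg, IEEE float32, multiplexed).

Written files carry movement-onset stimulus markers (S1-S4 encode task x hand)
plus a comment marker with run index and subject id, and round-trip through
MNE's BrainVision reader.
"""

from __future__ import annotations

import os

import numpy as np

from .io_prep import Recording, TASK_CODES

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by exobci synthetic session generator

[Common Infos]
Codepage=UTF-8
DataFile={data_file}
MarkerFile={marker_file}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={data_file}

[Marker Infos]
{marker_lines}
"""


def write_brainvision(rec: Recording, basename: str) -> str:
    """Write ``basename{.vhdr,.vmrk,.eeg}``; returns the .vhdr path."""
    base = os.path.splitext(basename)[0]
    stem = os.path.basename(base)
    vhdr, vmrk, eeg = base + ".vhdr", base + ".vmrk", base + ".eeg"

    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channel_labels)
    )
    with open(vhdr, "w", encoding="utf-8") as fh:
        fh.write(
            _VHDR_TEMPLATE.format(
                data_file=stem + ".eeg",
                marker_file=stem + ".vmrk",
                n_channels=len(rec.channel_labels),
                sampling_interval_us=int(round(1e6 / rec.sampling_rate)),
                channel_lines=ch_lines,
            )
        )

    run = rec.events[0].run if rec.events else 0
    markers = [
        'Mk1=New Segment,,1,1,0',
        f'Mk2=Comment,run={run};subject={rec.subject_id},1,1,0',
    ]
    for k, ev in enumerate(rec.events):
        code = TASK_CODES[(ev.task, ev.hand)]
        # BrainVision marker positions are 1-based
        markers.append(f"Mk{k + 3}=Stimulus,S{code:>3},{ev.sample + 1},1,0")
    with open(vmrk, "w", encoding="utf-8") as fh:
        fh.write(_VMRK_TEMPLATE.format(data_file=stem + ".eeg", marker_lines="\n".join(markers)))

    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: samples x channels
    return vhdr
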