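"""Standard 64-channel 10-20 montage labels and the frontal/parietal ROIs.

The label order follows the common 64-electrode BioSemi layout.  The two
regions of interest each contain 13 electrodes symmetrically surrounding
Fz (frontal) and Pz (parietal); models are always fit to all channels
and only the *results* are averaged over an ROI.
"""
from __future__ import annotations

__all__ = ["BIOSEMI64", "FRONTAL_ROI", "PARIETAL_ROI", "default_channel_names"]

BIOSEMI64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

FRONTAL_ROI = [
    "AF3", "AFz", "AF4", "F3", "F1", "Fz", "F2", "F4",
    "FC3", "FC1", "FCz", "FC2", "FC4",
]

PARIETAL_ROI = [
    "CP3", "CP1", "CPz", "CP2", "CP4", "P3", "P1", "Pz",
    "P2", "P4", "PO3", "POz", "PO4",
]


def default_channel_names(n_channels: int) -> list[str]:
    """Montage labels for 64 channels; generic names otherwise."""
    if n_channels == len(BIOSEMI64):
        return list(BIOSEMI64)
    return [f"ch{i:02d}" for i in range(n_channels)]
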