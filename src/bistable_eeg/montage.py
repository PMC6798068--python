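"""Electrode montage and analysis-location definitions.

The recording montage is a 24-electrode subset of the international 10-20
system: ten electrodes per hemisphere plus four midline sites, referenced at
FCz with ground at Fpz.  Analyses additionally use six virtual locations
(L1..L6), each the unweighted mean of an anatomical channel group, giving
30 analysis locations in total.
"""

from __future__ import annotations

#: Ordered 24-channel montage (left hemisphere, right hemisphere, midline).
MONTAGE_24: tuple[str, ...] = (
    "Fp1", "F7", "FC1", "C3", "T7", "CP1", "CP5", "TP9", "P3", "O1",
    "Fp2", "F8", "FC2", "C4", "T8", "CP2", "CP6", "TP10", "P4", "O2",
    "Fz", "Cz", "CPz", "Pz",
)

#: Anatomical channel groups.  L1/L2: frontal; L3/L4: rear; L5/L6: whole lobe.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "L1": ("Fp1", "F7", "FC1"),
    "L2": ("Fp2", "F8", "FC2"),
    "L3": ("TP9", "CP5", "CP1", "P3", "O1"),
    "L4": ("TP10", "CP6", "CP2", "P4", "O2"),
}
CHANNEL_GROUPS["L5"] = CHANNEL_GROUPS["L1"] + CHANNEL_GROUPS["L3"]
CHANNEL_GROUPS["L6"] = CHANNEL_GROUPS["L2"] + CHANNEL_GROUPS["L4"]

#: The 30 analysis locations: 24 electrodes followed by the 6 group locations.
LOCATIONS_30: tuple[str, ...] = MONTAGE_24 + tuple(CHANNEL_GROUPS)

GROUP_NAMES: tuple[str, ...] = tuple(CHANNEL_GROUPS)

REFERENCE = "FCz"
GROUND = "Fpz"
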