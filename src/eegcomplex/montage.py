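"""The 19-electrode 10-20 montage: canonical channel order and 2-D scalp layout."""

from __future__ import annotations

# Canonical acquisition order of the 19-channel 10-20 montage.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Schematic top-view scalp coordinates (nose up, left ear at x<0), unit head
# radius.  Used only for topographic export; not a physical digitization.
XY_1020: dict[str, tuple[float, float]] = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.43, 0.55), "Fz": (0.00, 0.50),
    "F4": (0.43, 0.55), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.00), "C3": (-0.50, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.50, 0.00), "T4": (1.00, 0.00),
    "T5": (-0.81, -0.59), "P3": (-0.43, -0.55), "Pz": (0.00, -0.50),
    "P4": (0.43, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "O2": (0.31, -0.95),
}

GROUPS: tuple[str, ...] = ("HC", "AD1", "AD2", "AD3")

#: Severity rank used to decide which contrast member is the positive class.
GROUP_SEVERITY: dict[str, int] = {"HC": 0, "AD1": 1, "AD2": 2, "AD3": 3}

NPI_SYMPTOMS: tuple[str, ...] = (
    "DEL", "HAL", "AG", "DEP", "ANX", "APA",
    "IRR", "EUP", "DIS", "ABE", "NIG", "APP",
)
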