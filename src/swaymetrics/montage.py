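"""Fixed 64-electrode 10-10 montage used for all EEG channels.

The cap layout is a standard extended 10-10 set with both mastoids (M1,
M2).  The label *order* is the canonical channel order of ``eeg.csv`` and
of every generated EEG array; code elsewhere indexes electrodes by label,
never by position, so the order itself carries no meaning beyond file
layout stability.
"""

EEG_MONTAGE_64: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8", "M1",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "M2",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO6", "PO8",
    "O1", "Oz", "O2",
)

assert len(EEG_MONTAGE_64) == 64

#: Lower-limb surface EMG channels: left/right tibialis anterior (TA),
#: gastrocnemius lateralis (GL) and soleus (S).
EMG_MUSCLES: tuple[str, ...] = ("L_TA", "L_GL", "L_S", "R_TA", "R_GL", "R_S")

#: Centre-of-pressure axes: medio-lateral (positive rightward) and
#: antero-posterior (positive anterior), in millimetres.
COP_AXES: tuple[str, ...] = ("ML", "AP")
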