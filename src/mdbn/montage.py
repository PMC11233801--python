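"""Default 32-electrode 10-20 montage used by the synthetic generator."""

#: 32 electrode labels from the extended 10-20 system.  Includes every
#: channel referenced by the default biomarker specification.
STANDARD_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T3", "C3", "Cz", "C4", "T4",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
    "A1", "A2",
]

assert len(STANDARD_32) == 32
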