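"""Static band-assignment lookup for the L-sorbose ring isomers.

Maps the (FTIR, Raman) wavenumber pairs of the fingerprint region to the
vibrational assignments of the four ring isomers.  Notation: nu =
stretching, delta = deformation; (CCO)* marks saccharide-ring modes.
Lookup table only — no automated assignment is performed.
"""

from __future__ import annotations

#: (nu_FTIR, nu_Raman) in cm^-1 -> {isomer: assignment}
BAND_ASSIGNMENTS: dict[tuple[int, int], dict[str, str]] = {
    (790, 726): {
        "alpha-sorbopyranose": "nu(CCO)*, delta(CH2)",
        "beta-sorbopyranose": "delta(OH), delta(CH2)",
        "alpha-sorbofuranose": "nu(CCO)*, delta(CH)",
    },
    (815, 822): {
        "beta-sorbopyranose": "nu(CCO)*, delta(CH)",
        "alpha-sorbofuranose": "delta(CH), delta(OH)",
        "beta-sorbofuranose": "nu(CCO)*, delta(CH)",
    },
    (876, 903): {
        "alpha-sorbopyranose": "delta(CH2), delta(OH)",
        "alpha-sorbofuranose": "nu(CCO)*, delta(CH), delta(CH2)",
    },
    (900, 910): {
        "beta-sorbopyranose": "nu(CC), delta(CH), delta(CH2)",
        "beta-sorbofuranose": "nu(CCO)*, delta(CH2), delta(OH)",
    },
    (930, 949): {
        "alpha-sorbopyranose": "nu(CCO)*, delta(CH2), delta(OH)",
        "beta-sorbofuranose": "delta(CH), delta(CH2)",
    },
    (981, 994): {
        "alpha-sorbopyranose": "nu(CCO)*, delta(CH), delta(OH)",
        "alpha-sorbofuranose": "delta(CH2), delta(OH)",
    },
    (1006, 1010): {
        "beta-sorbopyranose": "delta(CH2), delta(OH)",
        "beta-sorbofuranose": "nu(CCO)*, delta(CH2), delta(OH)",
    },
    (1011, 1020): {
        "beta-sorbopyranose": "nu(CCO)*, delta(OH)",
        "beta-sorbofuranose": "nu(CCO)*, delta(CH2), delta(OH)",
    },
    (1036, 1080): {
        "alpha-sorbopyranose": "nu(CCO)*, delta(OH)",
        "beta-sorbopyranose": "delta(CH2), delta(OH)",
        "alpha-sorbofuranose": "delta(CH2), delta(OH)",
        "beta-sorbofuranose": "delta(CH2), delta(OH)",
    },
    (3322, 3380): {
        "alpha-sorbopyranose": "nu(OH)",
        "beta-sorbopyranose": "nu(OH)",
        "alpha-sorbofuranose": "nu(OH)",
        "beta-sorbofuranose": "nu(OH)",
    },
}

#: marker bands used for the mutarotation kinetics (beta-isomer decay)
MARKER_BANDS = {"ftir_cm1": 815.0, "raman_cm1": 822.0}
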