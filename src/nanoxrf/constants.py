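"""Embedded X-ray physics constants for the supported element set.

Line energies and branching ratios are transcribed from standard X-ray
emission tables (values rounded to the eV level). The fluorescence
"production factors" ``K_PRODUCTION`` lump together the photoelectric mass
cross-section at the 17.5 keV excitation energy, the shell jump fraction and
the fluorescence yield of the excited shell: multiplying by areal density,
geometry and concentration yields detected line-group counts. They are
deliberately coarse (~10% level): the pipeline calibrates sensitivities
against a simulated reference standard, so only the realism of the count
levels matters, not the absolute accuracy of the factors.
"""

from __future__ import annotations

SUPPORTED_ELEMENTS = ("P", "S", "Ca", "Mn", "Fe", "Zn", "Br", "Pt")

# (series, energy_keV, raw relative intensity within the element's group)
# K-series for Z <= 35; L-series (La, Lb, Lg) for Pt.
EMISSION_LINES: dict[str, list[tuple[str, float, float]]] = {
    "P":  [("Ka", 2.0137, 1.000), ("Kb", 2.1391, 0.050)],
    "S":  [("Ka", 2.3078, 1.000), ("Kb", 2.4640, 0.060)],
    "Ca": [("Ka", 3.6909, 1.000), ("Kb", 4.0127, 0.128)],
    "Mn": [("Ka", 5.8988, 1.000), ("Kb", 6.4905, 0.135)],
    "Fe": [("Ka", 6.4039, 1.000), ("Kb", 7.0580, 0.134)],
    "Zn": [("Ka", 8.6389, 1.000), ("Kb", 9.5720, 0.138)],
    "Br": [("Ka", 11.9242, 1.000), ("Kb", 13.2914, 0.152)],
    "Pt": [("La", 9.4423, 1.000), ("Lb", 11.0707, 0.920), ("Lg", 12.9420, 0.210)],
}

# Principal (strongest) line energy per element, keV.
PRINCIPAL_LINE = {el: lines[0][1] for el, lines in EMISSION_LINES.items()}

# Fluorescence production factor at E0 = 17.5 keV, cm^2/g:
# tau(E0) * shell fraction * fluorescence yield.
K_PRODUCTION: dict[str, float] = {
    "P": 0.119,
    "S": 0.204,
    "Ca": 1.117,
    "Mn": 5.56,
    "Fe": 7.18,
    "Zn": 17.3,
    "Br": 36.1,
    "Pt": 24.5,  # L-shell excitation (K edge at 78.4 keV is out of reach)
}

# Soft-tissue-like organic matrix: mu/rho(E) ~ C_PE * E^-3 + C_INC  (cm^2/g, E keV)
MATRIX_MU_PE = 4500.0
MATRIX_MU_INCOHERENT = 0.18

# Beryllium detector window, same functional form.
BE_MU_PE = 570.0
BE_MU_INCOHERENT = 0.16
BE_DENSITY = 1.85  # g/cm^3

ELECTRON_REST_ENERGY_KEV = 510.999

# NIST SRM 1577c (bovine liver) certified mass fractions, transcribed from
# the certificate of analysis (mg/kg -> wt fraction).
NIST_1577C = {
    "P": 1.175e-2,
    "S": 7.49e-3,
    "Ca": 1.31e-4,
    "Mn": 1.046e-5,
    "Fe": 1.9794e-4,
    "Zn": 1.811e-4,
}


def group_normalized_lines(element: str) -> list[tuple[str, float, float]]:
    """Emission lines with relative intensities normalized to sum to 1."""
    lines = EMISSION_LINES[element]
    total = sum(rel for _, _, rel in lines)
    return [(series, energy, rel / total) for series, energy, rel in lines]
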