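"""Shared physical defaults for the QPI and Raman arms.

Values are the instrument/protocol constants of the study design this
package emulates: an 800-nm off-axis reflection phase microscope measuring
fibroblasts in double-pass transmission, and a 785-nm confocal Raman
microscope restricted to the biological fingerprint region.
"""

#: Dose groups in exposure order (minutes of UV at 1.02 W/m²: 0, 50, 100, 200).
DOSE_GROUPS = ("control", "T50", "T100", "T200")

#: Exposure time per group, minutes.
GROUP_MINUTES = {"control": 0.0, "T50": 50.0, "T100": 100.0, "T200": 200.0}

#: Specific refractive index increment, µm³/pg. Typical cellular value
#: 0.185 ± 0.002; converts integrated optical path delay to dry mass.
ALPHA_DEFAULT = 0.185

#: Centre wavelength of the phase-imaging source, µm (Δλ ≈ 17 nm ignored).
WAVELENGTH_DEFAULT = 0.8

#: Cell segmentation threshold on background-corrected phase, radians.
PHASE_THRESHOLD = 0.2

#: Raman fingerprint region, cm⁻¹.
FINGERPRINT_LO = 600.0
FINGERPRINT_HI = 1800.0

#: UV irradiance integrated over 280–400 nm, W/m².
UV_IRRADIANCE = 1.02

#: Marker / assignment band positions, cm⁻¹. 1000 (phenylalanine ring
#: breathing) and 1584 (guanine/adenine N–H bending) are the apoptosis
#: markers whose intensities respond to UV dose.
RAMAN_BANDS = {
    720: "nucleic acid",
    835: "tyrosine",
    1000: "phenylalanine (UV marker)",
    1004: "phenylalanine",
    1093: "nucleic acid backbone",
    1250: "amide III",
    1340: "nucleic acid",
    1440: "CH2 deformation (lipid/protein)",
    1576: "nucleic acid",
    1584: "DNA base N-H bending (UV marker)",
    1660: "amide I",
}
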