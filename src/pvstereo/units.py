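"""Centralized unit conversions.

Convention throughout the package: lengths in data files are micrometres,
areas are mm^2, volumes are mm^3 internally, and densities are cells/mm^3
in all outputs.  Every conversion between the micrometre and millimetre
scales goes through these helpers so the exponent lives in exactly one
place.
"""

UM_PER_MM = 1000.0


def um_to_mm(x):
    return x / UM_PER_MM


def um3_to_mm3(v):
    return v / UM_PER_MM**3


def disector_volume_mm3(frame_area_mm2, height_um):
    """Volume of one optical disector: frame area (mm^2) x guarded height (um)."""
    return frame_area_mm2 * um_to_mm(height_um)
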