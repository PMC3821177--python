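"""Region vocabulary for the thalamic nuclei analyzed.

The medial geniculate nucleus (MGN, auditory thalamus) is divided into
ventral, dorsal and magnocellular subdivisions; the lateral geniculate
nucleus (LGN, visual thalamus) has six layers, of which 1-2 are
magnocellular and 3-6 parvocellular.  Unknown labels are errors, never
warnings: a typo in a region name must not silently drop data.
"""

from __future__ import annotations

MGN_SUBDIVISIONS: tuple[str, ...] = ("vMGN", "dMGN", "mMGN")
LGN_LAYERS: tuple[str, ...] = ("LGN1", "LGN2", "LGN3", "LGN4", "LGN5", "LGN6")

#: The nine regions densities are estimated for.
REGIONS: tuple[str, ...] = MGN_SUBDIVISIONS + LGN_LAYERS

#: Pooled layer groups used for magno/parvocellular regressions.
REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "LGN_magno": ("LGN1", "LGN2"),
    "LGN_parvo": ("LGN3", "LGN4", "LGN5", "LGN6"),
}


def validate_region(name: str) -> str:
    """Return *name* if it is a known region, else raise ``ValueError``."""
    if name not in REGIONS:
        raise ValueError(
            f"unknown subdivision {name!r}; expected one of {', '.join(REGIONS)}"
        )
    return name
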