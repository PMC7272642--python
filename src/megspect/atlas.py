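"""Cortical parcellation labels, frequency bands and canonical orderings.

The analysis grid is 5 frequency bands x 68 cortical regions (34 per
hemisphere, gyral parcellation of the Desikan-Killiany atlas), with six
derived value types per cell.  Every table and feature vector in the
package is ordered by the constants defined here so that outputs are
reproducible column-for-column.
"""

from __future__ import annotations

# 34 gyral regions per hemisphere (Desikan-Killiany), atlas order.
DESIKAN_KILLIANY_34: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "frontalpole",
    "temporalpole",
    "transversetemporal",
    "insula",
)

#: Analysis bands in canonical order: theta and alpha are split into
#: sub-bands; delta (<4 Hz) and gamma (>20 Hz) are outside the analysis range.
BAND_EDGES_HZ: dict[str, tuple[float, float]] = {
    "theta1": (4.0, 6.0),
    "theta2": (6.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta": (13.0, 20.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BAND_EDGES_HZ)

CONDITIONS: tuple[str, ...] = ("EC", "EO")
GROUPS: tuple[str, ...] = ("AD", "NC")

#: The six per-(band, region) value types, canonical order: absolute power
#: under each condition, its whole-cerebral-normalized (WCN) z-score, the
#: EC-EO reactivity difference, and the WCN of that difference.
VALUE_TYPES: tuple[str, ...] = (
    "absEC",
    "absEO",
    "wcnEC",
    "wcnEO",
    "diffECEO",
    "wcnDiff",
)


def region_labels(n_regions: int = 68) -> tuple[str, ...]:
    """Canonical region labels for an ``n_regions``-patch parcellation.

    For 68 regions these are the Desikan-Killiany names prefixed with the
    hemisphere, left hemisphere first (``lh_bankssts`` ... ``rh_insula``).
    Other even counts use numbered hemispheric patches; odd counts use a
    flat numbering.
    """
    if n_regions < 1:
        raise ValueError(f"n_regions must be >= 1, got {n_regions}")
    if n_regions == 68:
        return tuple(f"lh_{r}" for r in DESIKAN_KILLIANY_34) + tuple(
            f"rh_{r}" for r in DESIKAN_KILLIANY_34
        )
    if n_regions % 2 == 0:
        half = n_regions // 2
        return tuple(f"lh_region{i:02d}" for i in range(half)) + tuple(
            f"rh_region{i:02d}" for i in range(half)
        )
    return tuple(f"region{i:02d}" for i in range(n_regions))
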