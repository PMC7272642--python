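"""Per-subject spectral features: absolute power, WCN z-scores, reactivity.

For every band the 68 regional absolute powers yield six value types:

* ``absEC`` / ``absEO`` -- regional absolute power under each condition;
* ``wcnEC`` / ``wcnEO`` -- the whole-cerebral-normalized (WCN) power, the
  z-score of a region against the mean and population SD of all regions,
  which removes inter-individual scale differences;
* ``diffECEO`` -- the EC-EO reactivity difference (eyes-closed minus
  eyes-open absolute power);
* ``wcnDiff`` -- the WCN z-score of that difference.

With the default 5 bands x 68 regions this is 6 x 5 x 68 = 2,040 features
per subject, flattened in a fixed, documented order: value type major,
then band (theta1, theta2, alpha1, alpha2, beta), then region (left
hemisphere first, atlas order).  Feature names read
``wcnEC.alpha1.rh_supramarginal``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import BAND_NAMES, VALUE_TYPES


class DegenerateDispersionError(ValueError):
    """All regional values equal: the WCN z-score is undefined."""


def wcn_normalize(region_values, ddof: int = 0) -> np.ndarray:
    """Whole-cerebral normalization: z-score across regions.

    (value in region a - mean over all regions) / (SD over all regions),
    population SD by default.  Raises
    :class:`DegenerateDispersionError` when the regional values have zero
    dispersion rather than returning silent zeros.
    """
    x = np.asarray(region_values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of at least 2 regional values")
    if not np.all(np.isfinite(x)):
        raise ValueError("regional values must be finite")
    sd = x.std(ddof=ddof)
    # relative floor: rounding noise on a constant vector is not dispersion
    if sd <= 1e-12 * np.abs(x).max():
        raise DegenerateDispersionError(
            "all regional values are equal; WCN z-score undefined"
        )
    return (x - x.mean()) / sd


def ec_eo_difference(power_ec, power_eo):
    """Elementwise eyes-closed minus eyes-open regional power.

    Accepts aligned pandas Series (indexes must match exactly) or plain
    arrays of equal length.
    """
    if isinstance(power_ec, pd.Series) and isinstance(power_eo, pd.Series):
        if not power_ec.index.equals(power_eo.index):
            raise ValueError("EC and EO region indexes do not match")
        return power_ec - power_eo
    a = np.asarray(power_ec, float)
    b = np.asarray(power_eo, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def feature_names(
    bands: tuple[str, ...] = BAND_NAMES, regions: tuple[str, ...] | None = None
) -> pd.Index:
    """Canonical feature names, value-type major then band then region."""
    if regions is None:
        from .atlas import region_labels

        regions = region_labels(68)
    return pd.Index(
        [
            f"{vt}.{band}.{region}"
            for vt in VALUE_TYPES
            for band in bands
            for region in regions
        ],
        name="feature",
    )


def parse_feature_name(name: str) -> tuple[str, str, str]:
    """Split a canonical feature name into (value_type, band, region)."""
    vt, band, region = name.split(".", 2)
    if vt not in VALUE_TYPES:
        raise ValueError(f"unknown value type in feature name {name!r}")
    return vt, band, region


def _subject_grid(table: pd.DataFrame, subject_id: str) -> pd.DataFrame:
    sub = table[table["subject_id"] == subject_id]
    if sub.empty:
        raise KeyError(f"subject {subject_id!r} not in region power table")
    return sub


def assemble_features(
    table: pd.DataFrame,
    subject_id: str,
    bands: tuple[str, ...] = BAND_NAMES,
    regions: tuple[str, ...] | None = None,
) -> pd.Series:
    """Build one subject's canonical feature vector from a region power table.

    ``table`` is tidy with columns subject_id, condition, band, region,
    power (one row per cell).  Raises with the name of any missing
    (condition, band, region) cell.  The result for the default grid has
    exactly 6 x 5 x 68 = 2,040 entries.
    """
    sub = _subject_grid(table, subject_id)
    if regions is None:
        regions = tuple(pd.unique(sub["region"]))
    grid = sub.set_index(["condition", "band", "region"])["power"]
    if grid.index.duplicated().any():
        raise ValueError(f"duplicate cells for subject {subject_id!r}")
    grid = grid.sort_index()

    def band_vector(condition: str, band: str) -> np.ndarray:
        try:
            vec = grid.loc[(condition, band)].reindex(list(regions))
        except KeyError:
            raise KeyError(
                f"missing condition/band ({condition}, {band}) "
                f"for subject {subject_id!r}"
            ) from None
        if vec.isna().any():
            gap = vec.index[vec.isna()][0]
            raise KeyError(
                f"missing region {gap!r} in ({condition}, {band}) "
                f"for subject {subject_id!r}"
            )
        return vec.to_numpy()

    blocks: dict[str, list[np.ndarray]] = {vt: [] for vt in VALUE_TYPES}
    for band in bands:
        abs_ec = band_vector("EC", band)
        abs_eo = band_vector("EO", band)
        diff = ec_eo_difference(abs_ec, abs_eo)
        blocks["absEC"].append(abs_ec)
        blocks["absEO"].append(abs_eo)
        blocks["wcnEC"].append(wcn_normalize(abs_ec))
        blocks["wcnEO"].append(wcn_normalize(abs_eo))
        blocks["diffECEO"].append(diff)
        blocks["wcnDiff"].append(wcn_normalize(diff))
    values = np.concatenate([np.concatenate(blocks[vt]) for vt in VALUE_TYPES])
    return pd.Series(
        values, index=feature_names(bands, tuple(regions)), name=subject_id
    )


def assemble_feature_table(
    table: pd.DataFrame,
    subjects: pd.DataFrame,
    bands: tuple[str, ...] = BAND_NAMES,
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Feature matrix for a cohort: one row per subject.

    ``subjects`` has columns subject_id and group; the result carries
    subject_id and group as the first two columns followed by the
    canonical features.
    """
    rows = [
        assemble_features(table, sid, bands=bands, regions=regions)
        for sid in subjects["subject_id"]
    ]
    out = pd.DataFrame(rows)
    out.insert(0, "group", subjects["group"].to_numpy())
    out.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    return out.reset_index(drop=True)


def features_from_truth(
    true_amplitudes: pd.DataFrame,
    subjects: pd.DataFrame,
    bands: tuple[str, ...] = BAND_NAMES,
    regions: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Feature matrix computed directly from ground-truth amplitudes.

    Treats the generator's drawn per-subject regional amplitudes as the
    region power table, bypassing the forward/inverse stages; used for
    fast statistical calibration studies.
    """
    table = true_amplitudes.rename(columns={"amplitude": "power"})
    return assemble_feature_table(table, subjects, bands=bands, regions=regions)
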