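"""Background subtraction and control normalization of raw luminescence.

Relative viability is computed per plate: the mean luminescence of the
plate's blank wells is subtracted from every well, and each
background-subtracted value is divided by the mean background-subtracted
value of the reference wells (untransfected mock wells, or non-targeting
scrambled wells). Negative post-subtraction values are clamped to zero and
flagged rather than propagated into the scoring stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from arrayscreen.errors import MissingReferenceError, SchemaError
from arrayscreen.screen_io import WellRecord, plate_map_frame

logger = logging.getLogger(__name__)

NORMALIZED_COLUMNS = [
    "plate_id", "well", "gene_symbol", "guide_id", "content_type",
    "replicate", "viability_vs_mock", "viability_vs_scrambled", "qc_flags",
]


def _as_map_frame(plate_map) -> pd.DataFrame:
    if isinstance(plate_map, pd.DataFrame):
        return plate_map
    if plate_map and isinstance(plate_map[0], WellRecord):
        return plate_map_frame(plate_map)
    raise TypeError("plate_map must be a DataFrame or list of WellRecord")


def estimate_background(
    readouts: pd.DataFrame,
    plate_map,
    override: float | None = None,
) -> dict[str, float]:
    """Per-plate background level.

    The background is the mean raw luminescence over each plate's blank
    wells. An explicit ``override`` takes precedence; a plate with no blanks
    and no override falls back to 0 with a logged warning.
    """
    pm = _as_map_frame(plate_map)
    merged = readouts.merge(pm, on=["plate_id", "well"], how="left")
    backgrounds: dict[str, float] = {}
    for plate_id, grp in merged.groupby("plate_id", sort=False):
        if override is not None:
            backgrounds[plate_id] = float(override)
            continue
        blanks = grp.loc[grp["content_type"] == "blank", "raw_luminescence"]
        if blanks.empty:
            logger.warning(
                "plate %s has no blank wells and no background override; "
                "using background = 0", plate_id,
            )
            backgrounds[plate_id] = 0.0
        else:
            backgrounds[plate_id] = float(blanks.mean())
    return backgrounds


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Transform raw plate readouts into relative viability.

    Parameters
    ----------
    reference : {"mock", "scrambled"}
        Control wells whose plate mean defines viability 1.0. Each plate
        needs at least ``min_reference_wells`` of this type.
    background_override : float, optional
        Fixed background to use instead of the blank-well mean.
    min_reference_wells : int, default 2
        Minimum reference wells per plate.

    Fitted attributes
    -----------------
    background_ : dict plate_id -> background level
    reference_mean_ : dict (plate_id, reference) -> mean background-subtracted
        reference luminescence
    """

    def __init__(
        self,
        reference: str = "mock",
        background_override: float | None = None,
        min_reference_wells: int = 2,
    ):
        self.reference = reference
        self.background_override = background_override
        self.min_reference_wells = min_reference_wells

    def fit(self, readouts: pd.DataFrame, plate_map=None):
        if self.reference not in ("mock", "scrambled"):
            raise ValueError("reference must be 'mock' or 'scrambled'")
        pm = _as_map_frame(plate_map)
        unmapped = readouts.merge(
            pm[["plate_id", "well", "content_type"]],
            on=["plate_id", "well"], how="left",
        )["content_type"].isna()
        if unmapped.any():
            bad = readouts.loc[unmapped.to_numpy()].iloc[0]
            raise SchemaError(
                f"readout well {bad['plate_id']}/{bad['well']} absent from "
                "the plate map"
            )
        self.plate_map_ = pm
        self.background_ = estimate_background(
            readouts, pm, override=self.background_override
        )
        merged = readouts.merge(pm, on=["plate_id", "well"], how="left")
        self.reference_mean_ = {}
        for plate_id, grp in merged.groupby("plate_id", sort=False):
            bg = self.background_[plate_id]
            for ref in ("mock", "scrambled"):
                vals = grp.loc[
                    grp["content_type"] == ref, "raw_luminescence"
                ]
                if len(vals) > 0:
                    self.reference_mean_[(plate_id, ref)] = float(
                        (vals - bg).mean()
                    )
            if (
                (merged["plate_id"] == plate_id)
                & (merged["content_type"] == self.reference)
            ).sum() < self.min_reference_wells:
                raise MissingReferenceError(
                    f"plate {plate_id}: fewer than "
                    f"{self.min_reference_wells} {self.reference} wells"
                )
        return self

    def transform(self, readouts: pd.DataFrame) -> pd.DataFrame:
        """Normalized viability table, one row per well present in
        ``readouts``. Wells on the plate map but absent from the readouts
        are dropped (failed wells), not errored."""
        pm = self.plate_map_
        merged = readouts.merge(pm, on=["plate_id", "well"], how="left")
        rows = []
        for tup in merged.itertuples(index=False):
            bg = self.background_[tup.plate_id]
            net = tup.raw_luminescence - bg
            flags = set()
            if net < 0:
                net = 0.0
                flags.add("clamped_negative")
            row = {
                "plate_id": tup.plate_id,
                "well": tup.well,
                "gene_symbol": tup.gene_symbol,
                "guide_id": tup.guide_id,
                "content_type": tup.content_type,
                "replicate": tup.replicate,
            }
            for ref, colname in (
                ("mock", "viability_vs_mock"),
                ("scrambled", "viability_vs_scrambled"),
            ):
                denom = self.reference_mean_.get((tup.plate_id, ref))
                if denom is None or denom <= 0:
                    row[colname] = np.nan
                    flags.add("missing_reference")
                else:
                    row[colname] = net / denom
            row["qc_flags"] = ";".join(sorted(flags))
            rows.append(row)
        return pd.DataFrame(rows, columns=NORMALIZED_COLUMNS)

    def fit_transform(self, readouts, plate_map=None, **kwargs):
        return self.fit(readouts, plate_map).transform(readouts)


def normalize_plate(
    readouts: pd.DataFrame,
    plate_map,
    reference: str = "mock",
    background_override: float | None = None,
) -> pd.DataFrame:
    """Functional wrapper around :class:`PlateNormalizer`."""
    return PlateNormalizer(
        reference=reference, background_override=background_override
    ).fit_transform(readouts, plate_map)


def summarize_replicates(
    normalized: pd.DataFrame,
    value_column: str = "viability_vs_mock",
    cell_line: str | None = None,
) -> pd.DataFrame:
    """Per-guide mean, sample standard deviation and replicate count.

    Grouping is by (gene_symbol, guide_id) across replicate wells; the
    standard deviation uses the n-1 denominator and is NaN for n = 1.
    """
    df = normalized.loc[
        normalized["content_type"].isin(
            ["gene", "scrambled", "positive_control"]
        )
    ]
    out = (
        df.groupby(["content_type", "gene_symbol", "guide_id"], sort=False)[
            value_column
        ]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    if cell_line is not None:
        out.insert(0, "cell_line", cell_line)
    return out
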