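"""Ambient pesticide exposure scoring from application records and address histories.

The exposure model follows the GIS buffer approach used with California
Pesticide Use Reporting (CA-PUR) style data: every recorded application is a
point event (field centroid) with an amount in pounds over a treated acreage;
a participant's exposure to a chemical in a calendar year is the sum of
pounds-per-acre over all applications of that chemical falling within a
fixed-radius buffer (default 500 m, boundary inclusive) of any address the
participant occupied that year.  Residential and workplace buffers are pooled.

Annual exposures are averaged over the fixed window 1974 to the year of blood
draw (zero years count in the denominator), dichotomized at the per-chemical
median among healthy controls, and summed into per-group chemical counts
("copper count", "OP count") — the exposure scores used as EWAS predictors.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_START_YEAR = 1974

APPLICATION_COLUMNS = ("chemical_code", "year", "pounds", "acres", "x", "y")
ADDRESS_COLUMNS = ("participant_id", "x", "y", "start_year", "end_year", "kind")


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def annual_buffer_exposure(
    applications: pd.DataFrame,
    addresses: pd.DataFrame,
    radius_m: float = 500.0,
    participants: Iterable[str] | None = None,
    rate: bool = True,
) -> pd.DataFrame:
    """Sum in-buffer application intensity per participant, chemical and year.

    Parameters
    ----------
    applications
        One row per application event with columns ``chemical_code, year,
        pounds, acres, x, y`` (planar meters).
    addresses
        One row per address interval with columns ``participant_id, x, y,
        start_year, end_year, kind``; intervals are inclusive in years.
    radius_m
        Buffer radius in meters; an application at exactly ``radius_m`` is
        inside the buffer (boundary inclusive).
    participants
        Optional full roster.  Members without a single address interval are
        excluded with a logged warning (they cannot be scored).
    rate
        If True (default) the contribution of an application is
        ``pounds / acres`` (lbs/acre); if False, raw pounds.

    Returns
    -------
    DataFrame with columns ``participant_id, chemical_code, year, exposure``
    containing only nonzero entries (a sparse mapping; absent means 0).
    """
    _check_columns(applications, APPLICATION_COLUMNS, "applications")
    _check_columns(addresses, ADDRESS_COLUMNS, "addresses")
    if radius_m < 0:
        raise ValueError("radius_m must be nonnegative")

    if participants is not None:
        roster = list(participants)
        with_address = set(addresses["participant_id"])
        missing = [p for p in roster if p not in with_address]
        if missing:
            logger.warning(
                "excluding %d participant(s) with empty address history: %s",
                len(missing), ", ".join(map(str, missing[:10])),
            )

    app_x = applications["x"].to_numpy(float)
    app_y = applications["y"].to_numpy(float)
    app_year = applications["year"].to_numpy(int)
    app_chem = applications["chemical_code"].to_numpy()
    amount = applications["pounds"].to_numpy(float)
    if rate:
        amount = amount / applications["acres"].to_numpy(float)

    r2 = float(radius_m) ** 2
    pid_parts: list[np.ndarray] = []
    chem_parts: list[np.ndarray] = []
    year_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []

    # Sort address intervals so output accumulation order never depends on
    # input row order (permutation safety).
    addr = addresses.sort_values(
        ["participant_id", "start_year", "end_year", "x", "y", "kind"],
        kind="mergesort",
    )
    for row in addr.itertuples(index=False):
        d2 = (app_x - row.x) ** 2 + (app_y - row.y) ** 2
        mask = (d2 <= r2) & (app_year >= row.start_year) & (app_year <= row.end_year)
        if not mask.any():
            continue
        k = int(mask.sum())
        pid_parts.append(np.repeat(row.participant_id, k))
        chem_parts.append(app_chem[mask])
        year_parts.append(app_year[mask])
        val_parts.append(amount[mask])

    if not pid_parts:
        return pd.DataFrame(
            columns=["participant_id", "chemical_code", "year", "exposure"]
        )
    long = pd.DataFrame(
        {
            "participant_id": np.concatenate(pid_parts),
            "chemical_code": np.concatenate(chem_parts),
            "year": np.concatenate(year_parts),
            "exposure": np.concatenate(val_parts),
        }
    )
    out = (
        long.groupby(["participant_id", "chemical_code", "year"], sort=True)["exposure"]
        .sum()
        .reset_index()
    )
    return out


def average_window(
    annual: pd.DataFrame,
    blood_draw_year: Mapping[str, int] | pd.Series,
    chemicals: Sequence,
    start_year: int = WINDOW_START_YEAR,
) -> pd.DataFrame:
    """Average annual exposure over the window ``start_year..blood_draw_year``.

    Zero-exposure years count in the denominator: the divisor for participant
    *i* is ``blood_draw_year[i] - start_year + 1`` regardless of how many
    years saw any application.

    Returns a wide DataFrame (participants x chemicals) of window averages,
    with explicit zeros, indexed by participant id.  Participants come from
    ``blood_draw_year``; chemicals from the ``chemicals`` list, so fully
    unexposed participants and never-applied chemicals appear as zero rows
    and columns.
    """
    draw = pd.Series(blood_draw_year)
    if (draw < start_year).any():
        bad = draw.index[draw < start_year].tolist()
        raise ValueError(f"blood_draw_year before {start_year} for: {bad}")
    chems = list(chemicals)
    profiles = pd.DataFrame(0.0, index=draw.index, columns=chems)
    profiles.index.name = "participant_id"
    if len(annual):
        ann = annual.merge(
            draw.rename("draw_year"), left_on="participant_id", right_index=True
        )
        ann = ann[(ann["year"] >= start_year) & (ann["year"] <= ann["draw_year"])]
        sums = ann.pivot_table(
            index="participant_id",
            columns="chemical_code",
            values="exposure",
            aggfunc="sum",
            fill_value=0.0,
        )
        common = [c for c in chems if c in sums.columns]
        profiles.loc[sums.index, common] = sums[common].to_numpy()
    denom = (draw - start_year + 1).astype(float)
    return profiles.div(denom, axis=0)


class CountScores(NamedTuple):
    """Copper/OP chemical counts with the indicators and thresholds behind them."""

    counts: pd.DataFrame       # participant x [copper_count, op_count]
    indicators: pd.DataFrame   # participant x chemical, {0, 1}
    thresholds: pd.Series      # chemical -> control median of window averages


def dichotomize_and_count(
    profiles: pd.DataFrame,
    control_ids: Iterable[str],
    copper_codes: Sequence,
    op_codes: Sequence,
) -> CountScores:
    """Dichotomize window-average exposures at control medians and count.

    For each chemical the threshold is the median window-average exposure
    among healthy controls (midpoint convention for even counts).  A
    participant's indicator is 1 iff their average is *strictly* greater than
    the threshold (ties score 0); the copper/OP count is the sum of
    indicators over the chemicals in each group.
    """
    controls = list(control_ids)
    if not controls:
        raise ValueError("control_ids must be non-empty")
    missing = [c for c in controls if c not in profiles.index]
    if missing:
        raise ValueError(f"control ids absent from profiles: {missing}")
    for group, codes in (("copper", copper_codes), ("op", op_codes)):
        absent = [c for c in codes if c not in profiles.columns]
        if absent:
            raise ValueError(f"{group} chemicals absent from profiles: {absent}")

    thresholds = profiles.loc[controls].median(axis=0)
    flat = profiles.std(axis=0) == 0
    if flat.any():
        logger.info(
            "%d chemical(s) with zero variance everywhere; indicators are 0",
            int(flat.sum()),
        )
    indicators = profiles.gt(thresholds, axis=1).astype(int)
    counts = pd.DataFrame(
        {
            "copper_count": indicators[list(copper_codes)].sum(axis=1),
            "op_count": indicators[list(op_codes)].sum(axis=1),
        },
        index=profiles.index,
    )
    counts.index.name = "participant_id"
    return CountScores(counts=counts, indicators=indicators, thresholds=thresholds)
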