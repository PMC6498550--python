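"""Cold-deck imputation of missing interval-cancer f-Hb.

Interval cancers surface clinically between screens, so their f-Hb at
diagnosis was never measured.  Under the bleeding-phenotype premise a
missed cancer resembles a screen-detected cancer of the same sex and age
at its detecting screen, so each interval cancer receives an observed
f-Hb value donated by a screen-detected CRC from the matched
(sex, age band) cell, drawn uniformly with replacement from a fixed donor
pool — no model smoothing, imputed values are always observed values.

Empty matched cells degrade along a deterministic, logged fallback
ladder: adjacent age bands (one band outward per level), then same sex at
any age, then any donor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AGE_BANDS


@dataclass
class DonorPool:
    """Observed f-Hb values of screen-detected CRCs, partitioned by (sex, age band)."""

    cells: dict[tuple[str, str], np.ndarray]

    @property
    def n_donors(self) -> int:
        return int(sum(len(v) for v in self.cells.values()))

    def donors_for(self, sex: str, age_band: str) -> tuple[np.ndarray, int]:
        """Donor values for a cell, with the fallback level used.

        Level 0: exact (sex, age band) match; level 1..: age band widened
        by one adjacent band per level (same sex); next: same sex, any
        age; last: any donor.  Raises if the pool is empty altogether.
        """
        exact = self.cells.get((sex, age_band))
        if exact is not None and len(exact):
            return exact, 0
        i = AGE_BANDS.index(age_band)
        for width in range(1, len(AGE_BANDS)):
            bands = [
                AGE_BANDS[j]
                for j in range(max(0, i - width), min(len(AGE_BANDS), i + width + 1))
            ]
            vals = np.concatenate(
                [self.cells.get((sex, b), np.empty(0)) for b in bands]
            )
            if len(vals):
                return vals, width
        same_sex = np.concatenate(
            [v for (s, _), v in self.cells.items() if s == sex] or [np.empty(0)]
        )
        if len(same_sex):
            return same_sex, len(AGE_BANDS)
        any_donor = (
            np.concatenate(list(self.cells.values())) if self.cells else np.empty(0)
        )
        if len(any_donor):
            return any_donor, len(AGE_BANDS) + 1
        raise ValueError("donor pool exhausted: no screen-detected CRC donors at all")


def build_donor_pool(records: pd.DataFrame) -> DonorPool:
    """Collect f-Hb of prevalent and subsequent screen-detected CRCs by (sex, age band)."""
    donors = records.loc[
        (records["status"] == "crc")
        & records["detection_mode"].isin(["prevalent_screen", "subsequent_screen"])
    ]
    if len(donors) == 0:
        raise ValueError(
            "no screen-detected CRC donors in the records; "
            "a larger cohort is needed to build a donor pool"
        )
    cells = {
        (sex, band): grp["fhb_std"].to_numpy(dtype=float)
        for (sex, band), grp in donors.groupby(["sex", "age_band"], sort=True)
    }
    return DonorPool(cells=cells)


def impute_interval_fhb(
    records: pd.DataFrame, pool: DonorPool, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill absent interval-cancer f-Hb with seeded cold-deck draws.

    Returns the imputed copy of ``records`` (row count and non-interval
    rows unchanged; interval rows get fhb_std/fhb_raw filled and FIT
    positivity re-derived) and an audit log with one row per imputation:
    record index, matched cell, fallback level, donated value.
    """
    rng = np.random.default_rng(seed)
    out = records.copy()
    interval_idx = out.index[out["detection_mode"] == "interval"]
    audit_rows = []
    for idx in interval_idx:
        sex = out.at[idx, "sex"]
        band = out.at[idx, "age_band"]
        donors, level = pool.donors_for(sex, band)
        value = float(donors[rng.integers(len(donors))])
        out.at[idx, "fhb_std"] = value
        audit_rows.append(
            {
                "record_index": idx,
                "subject_id": out.at[idx, "subject_id"],
                "sex": sex,
                "age_band": band,
                "fallback_level": level,
                "donor_fhb": value,
                "seed": seed,
            }
        )
    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "record_index",
            "subject_id",
            "sex",
            "age_band",
            "fallback_level",
            "donor_fhb",
            "seed",
        ],
    )
    return out, audit
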