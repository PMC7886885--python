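"""Published per-species reference values bundled for cross-checks.

Mean organelle morphometrics (three cells per species, mean ± s.d.)
reported by a comparative FIB-SEM study of phytoplankton, for the four
taxa whose plastids contain a pyrenoid, plus the low-light/high-light
occupancy comparison for the diatom. These tables carry species-level
means only (the underlying per-cell tables are distributed as that study's
supplementary data and are not bundled); they support recomputing derived
ratios and condition comparisons, not refitting per-cell correlations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "published_organelle_means",
    "published_light_acclimation",
    "pyrenoid_plastid_ratios",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("fibmorph.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def published_organelle_means() -> pd.DataFrame:
    """Per-species plastid and pyrenoid volumes (um^3, mean ± sd) and the
    reported pyrenoid/plastid volume ratio (%)."""
    return _load("published_organelle_means.csv")


def published_light_acclimation() -> pd.DataFrame:
    """Diatom organelle occupancy (% of cell volume) under low light (LL)
    and high light (HL), mean ± sd over three cells."""
    return _load("published_light_acclimation.csv")


def pyrenoid_plastid_ratios() -> pd.DataFrame:
    """Recompute the pyrenoid/plastid volume ratio from the published mean
    volumes and set it against the reported ratio.

    The reported ratio is the mean of per-cell ratios while the
    recomputation is a ratio of means, so exact agreement is not expected;
    the comparison column expresses the difference in units of the
    reported standard deviation.
    """
    df = published_organelle_means().copy()
    df["recomputed_pct"] = 100.0 * df["pyrenoid_volume_um3"] / df["plastid_volume_um3"]
    df["deviation_sd"] = (
        df["recomputed_pct"] - df["pyrenoid_plastid_pct"]
    ) / df["pyrenoid_plastid_pct_sd"]
    return df
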