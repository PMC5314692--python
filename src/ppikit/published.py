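"""Printed reference figures and their arithmetic-consistency checks.

The scoring scheme this toolkit implements was introduced with a release
comparison of a large integrated human interactome compendium. The
printed star-tier count table and negative-reference overlap counts ship
with the package as plain data; this module recomputes the derived
quantities (tier sums, medium-and-above totals, increase percentages,
false-positive ratio) from the raw counts so that the printed derived
values can be checked for internal consistency.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

TIERS = ("all", "5", "4", "3", "2", "1")
MEDIUM_AND_ABOVE = ("3", "4", "5")

#: Size of the manually curated stringent negative reference set.
NEGATIVE_REFERENCE_SIZE = 1991

#: Printed overlap counts between several interactomes and that negative set.
NEGATIVE_OVERLAPS = {"v2": 871, "v1": 309, "string": 894, "biogrid": 401}

#: Printed share of the negative reference covered by the curated database.
PRINTED_BIOGRID_NEGATIVE_SHARE_PCT = 20.14

#: Printed medium-and-above (3/4/5-star) totals for the two releases.
PRINTED_MEDIUM_AND_ABOVE = {"v1": 142523, "v2": 640748}


def load_release_counts() -> pd.DataFrame:
    """The shipped tier-count table, indexed by tier label."""
    path = resources.files("ppikit").joinpath("data/release_tier_counts.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"tier": str})
    return df.set_index("tier")


def tier_sum(df: pd.DataFrame, release: str) -> int:
    """Sum of the five per-tier counts for one release column."""
    col = f"{release}_count"
    return int(df.loc[[t for t in TIERS if t != "all"], col].sum())


def medium_and_above(df: pd.DataFrame, release: str) -> int:
    """Sum of the 3-, 4- and 5-star counts for one release column."""
    return int(df.loc[list(MEDIUM_AND_ABOVE), f"{release}_count"].sum())


def increase_pct(df: pd.DataFrame, tier: str) -> float:
    """Recomputed v2/v1 increase ratio, in percent, for one tier row."""
    row = df.loc[tier]
    return 100.0 * float(row["v2_count"]) / float(row["v1_count"])


def false_positive_ratio(db: str = "v2") -> float:
    """Negative-set overlap divided by database size (E = O / N)."""
    df = load_release_counts()
    n = tier_sum(df, db)
    return NEGATIVE_OVERLAPS[db] / n


def negative_share_pct(db: str) -> float:
    """Share of the negative reference found in a database, in percent."""
    return 100.0 * NEGATIVE_OVERLAPS[db] / NEGATIVE_REFERENCE_SIZE
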