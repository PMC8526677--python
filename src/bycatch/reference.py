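"""Published observer-program and logbook summary counts, used as inputs.

These are the printed fleet/observer tallies for the 1992–2017 U.S. Atlantic
pelagic longline fishery (observer program and logbook databases).  The
confidential set-level records behind them are not available; the counts
themselves are public summary statistics and serve as arithmetic inputs for
context quantities such as effort-concentration shares.
"""

from __future__ import annotations

#: logbook sets examined / retained after information-matching filters
LOGBOOK_SETS_EXAMINED = 285_589
LOGBOOK_SETS_RETAINED = 273_002

#: logbook sets by zone (top-five effort zones)
LOGBOOK_TOP5_ZONE_SETS = {"GOM": 95_285, "MAB": 48_176, "FEC": 39_127,
                          "SAB": 33_794, "NEC": 20_304}

#: observer-program sets and seabird bycatch outcomes
OBSERVER_SETS = 19_811
OBSERVER_POSITIVE_SETS = 92
OBSERVER_BIRDS = 165

#: observer sets by zone (top-five coverage zones)
OBSERVER_TOP5_ZONE_SETS = {"GOM": 9_020, "MAB": 3_053, "SAB": 2_181,
                           "FEC": 2_052, "NEC": 1_235}

#: sets affected per mitigation scenario
SCENARIO_SETS = 5_000


def scenario_share_pct() -> float:
    """Share (%) of the logbook database affected by moving/removing 5,000 sets."""
    return 100.0 * SCENARIO_SETS / LOGBOOK_SETS_RETAINED


def observer_zero_share_pct() -> float:
    """Share (%) of observer sets with zero seabird bycatch."""
    return 100.0 * (OBSERVER_SETS - OBSERVER_POSITIVE_SETS) / OBSERVER_SETS


def logbook_top5_share_pct() -> float:
    """Share (%) of logbook effort in the five highest-effort zones."""
    return 100.0 * sum(LOGBOOK_TOP5_ZONE_SETS.values()) / LOGBOOK_SETS_RETAINED


def observer_top5_share_pct() -> float:
    """Share (%) of observer sets in the five most-covered zones."""
    return 100.0 * sum(OBSERVER_TOP5_ZONE_SETS.values()) / OBSERVER_SETS


def mean_positive_bycatch() -> float:
    """Mean birds per positive observer set."""
    return OBSERVER_BIRDS / OBSERVER_POSITIVE_SETS
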