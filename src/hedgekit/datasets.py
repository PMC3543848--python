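"""Published benchmark counts for off-label drug-use retrieval in OvidSP EMBASE.

A validation study of search filters for reports on off-label drug use
screened 6,785 unique records retrieved from MEDLINE and EMBASE, judged
4,067 relevant (the full gold standard) of which 3,846 were retrievable
within EMBASE (the internal gold standard), and published per-query and
cumulative-strategy retrieval counts.  Every percentage in those tables is
an exact function of the printed integer counts, so the tables double as a
reference surface for the metrics layer: recomputing each derivable cell
from the counts must reproduce the printed value at the printed precision.

Only integer counts and verbatim query strings are stored here; all
percentages are recomputed by :mod:`hedgekit.metrics`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "N_SCREENED",
    "N_FULL_GOLD",
    "N_INTERNAL_GOLD",
    "N_INTERNAL_RECENT",
    "N_DUPLICATE_PAIRS",
    "N_TRIPLICATES",
    "PAIRED_DB_TABLE",
    "top_queries_table",
    "sensitivity_maximizing_strategy",
    "precision_optimized_strategy",
]

#: unique records screened for relevance across both databases
N_SCREENED = 6785
#: relevant records across both databases (full gold standard)
N_FULL_GOLD = 4067
#: relevant records retrievable within EMBASE (internal gold standard)
N_INTERNAL_GOLD = 3846
#: internal gold-standard records published 2001-2011 (of 3846)
N_INTERNAL_RECENT = 3480
#: vendor-side duplicate clusters observed in the EMBASE snapshot
N_DUPLICATE_PAIRS = 206
N_TRIPLICATES = 2

#: paired retrieval of the full gold standard by the two database-specific
#: sensitivity-maximized strategies: (both, EMBASE-only, MEDLINE-only, neither)
PAIRED_DB_TABLE = {"a": 1942, "b": 1880, "c": 222, "d": 23}

# (query, n_relevant_retrieved, n_retrieved) — the 15 most sensitive single queries
_TOP_QUERIES = [
    ("off label*.af.", 3150, 3577),
    ("(off adj2 label*).mp.", 3131, 3589),
    ("(off adj1 label*).mp.", 3130, 3567),
    ("off label*.mp.", 3128, 3555),
    ("off label.af.", 3119, 3542),
    ("(off adj1 label).mp.", 3119, 3544),
    ("(off adj2 label).mp.", 3119, 3547),
    ("off label.mp.", 3117, 3540),
    ('"off label*".ab,ti.', 2306, 2696),
    ("off label.ab,ti.", 2293, 2679),
    ('"off label*".ab.', 1882, 2224),
    ("off label.ab.", 1870, 2208),
    ("(drug adj2 label adj2 us*).af.", 1587, 1719),
    ("(drug adj1 label adj1 us*).af.", 1581, 1710),
    ('"off label drug us*".af.', 1580, 1677),
]

# sensitivity-maximizing strategy: (query, cumulative relevant, cumulative retrieved)
_HSSS_SENS = [
    ("off label*.af.", 3150, 3577),
    ("(off adj1 label).mp.", 3152, 3581),
    ("(drug adj2 label adj2 us*).af.", 3153, 3617),
    ("unlicense*.af.", 3279, 4320),
    ("unapprove*.af.", 3445, 4635),
    ("(label adj3 indication*).af.", 3450, 4667),
    ("off li?en?e*.af.", 3509, 4742),
    ("((no* licen?ed for adj3 use*) not now licen?ed).af.", 3560, 4825),
    ("((inappropriate us* and indication) not (antibiotic* or antimicrobial)).af.", 3609, 4964),
    ("((appropriate* adj3 prescri*) and indication).af.", 3648, 5081),
    ("(outside adj3 licen?e*).af.", 3665, 5110),
    ("unlabel* us*.af.", 3692, 5140),
    ("labeled indication*.af.", 3703, 5169),
    ("(inappropriate indication*).af.", 3719, 5294),
    ("nonapprove*.af.", 3737, 5337),
    ("registered indication*.af.", 3752, 5367),
    ("offlabel*.af.", 3757, 5372),
    ("(out* adj4 licen?ed indication*).af.", 3759, 5376),
    ("(unlabel* adj3 indication*).af.", 3767, 5384),
    ("non fda approve*.af.", 3780, 5411),
    ("((no* licen?ed for adj3 indication*) not now licen?ed).af.", 3793, 5425),
    ("(appropriate indication adj3 us*).af.", 3796, 5432),
    ("(be???d* adj2 licen?ed indication*).af.", 3799, 5436),
    ("(us* without adj2 indication*).af.", 3804, 5445),
    ("(prescri* outside adj4 guideline*).af.", 3808, 5450),
    ("(out of label).af.", 3810, 5466),
    ("(improper adj1 indication*).af.", 3812, 5472),
    ("(inappropriate adj5 indication adj2 us*).af.", 3814, 5475),
    ("no* appropriate indication*.af.", 3815, 5482),
    ("(non evidence base* us*).af.", 3818, 5487),
    ("without proper indication*.af.", 3821, 5498),
    ("(or/1-31) or (drug* without adj2 indication*).af.", 3822, 5501),
]

# the long NOT-refined "unlicensed" query is reproduced verbatim from the
# published table, including its typographic artifacts (")or", "device*or",
# trailing ".af.,"): strategy files must load such lines unmodified
_UNLICENSED_NOT = (
    "(unlicensed not (unlicensed aide* or unlicensed assist* or unlicensed car* or "
    "(Unlicensed adj2 heal*)or unlicensed home* or (killer adj2 cell*) or "
    "(unlicensed adj2 individual*) or (unlicensed adj2 nurs*) or "
    "(unlicensed adj4 practi*) or (unlicensed adj2 physician*) or "
    "(unlicensed adj2 operat*) or (unlicensed adj2 person*) or "
    "unlicensed profession* or unlicensed rid* or (unlicensed adj3 staff*) or "
    "unlicensed therapist* or (unlicensed adj5 vaccine*) or unlicensed vendor* or "
    "(unlicensed adj2 work*) or (unlicensed adj2 employe*) or device*or dentist*or "
    "driver or driving or herbal or medical graduate* or motor* or pesticide*or "
    "premis*or prostitute*or restaurant*or veterinary or worker*)).af.,"
)

# sensitivity- and precision-maximizing strategy (final line NOTs out decoys)
_HSSS_PREC = [
    ("off label*.af.", 3150, 3577),
    (_UNLICENSED_NOT, 3272, 3858),
    ("(unapprove* adj2 us*).af.", 3331, 3947),
    ("(unapprove* adj5 indication*).af.", 3367, 3986),
    ("off li?en?e.af.", 3425, 4053),
    ("((no* licen?ed for adj3 use*) not now licen?ed).af.", 3476, 4136),
    ("(unapprove* adj2 drug*).af.", 3493, 4181),
    ("(outside adj3 licen?e*).af.", 3511, 4211),
    ("unlabel* us*.af.", 3538, 4241),
    ("labeled indication*.af.", 3549, 4270),
    ("nonapprove*.af.", 3569, 4317),
    ("registered indication*.af.", 3585, 4348),
    ("offlabel*.af.", 3590, 4353),
    ("(unlabel* adj3 indication*).af.", 3598, 4361),
    ("non fda approve*.af.", 3611, 4388),
    ("((no* licen?ed for adj3 indication*) not now licen?ed).af.", 3624, 4402),
    ("(appropriate indication adj3 us*).af.", 3630, 4413),
    ("(be???d* adj2 licen?ed indication*).af.", 3633, 4417),
    ("(us* without adj2 indication*).af.", 3638, 4428),
    ("(prescri* outside adj4 guideline*).af.", 3643, 4434),
    ("(inappropriate adj5 indication adj2 us*).af.", 3647, 4441),
    ("(non evidence base* us*).af.", 3650, 4446),
    ("(or/1-22) not (stent* or veterinar*).af.", 3635, 4158),
]

_COLS = ["query", "n_relevant_retrieved", "n_retrieved"]


def top_queries_table() -> pd.DataFrame:
    """The 15 highest-sensitivity single queries with their raw counts."""
    return pd.DataFrame(_TOP_QUERIES, columns=_COLS)


def sensitivity_maximizing_strategy() -> pd.DataFrame:
    """The 32-line sensitivity-maximized strategy with cumulative counts."""
    df = pd.DataFrame(_HSSS_SENS, columns=_COLS)
    df.insert(0, "line", range(1, len(df) + 1))
    return df


def precision_optimized_strategy() -> pd.DataFrame:
    """The 23-line sensitivity- and precision-maximized strategy (final line
    excludes stent/veterinary decoy records with a NOT clause)."""
    df = pd.DataFrame(_HSSS_PREC, columns=_COLS)
    df.insert(0, "line", range(1, len(df) + 1))
    return df
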